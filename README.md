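# sterolflux

Compartmental kinetic modelling of cholesterol/sterol transport between the
plasma membrane and endo-lysosomes in mammalian cells — built for analysing
fractional-fluorescence time courses of cholesterol analogs (such as DHE) in
control and NPC2-deficient fibroblasts, and for simulating how the
sterol-transfer activity of NPC2 shapes cellular cholesterol efflux.

## The model

The cell is described by four well-mixed sterol pools: the plasma membrane
(PM, amount *n*₁), recycling endosomes (RE, *n*₂), the limiting membrane of
late endosomes/lysosomes (LM, *n*₃) and the intraluminal vesicles inside
them (ILV, *n*₄). Transport is first order:

```
dn₁/dt = −k₁n₁ + k₃n₃
dn₂/dt =  k₁n₁ − k₂n₂
dn₃/dt =  k₂n₂ − (k₃+k₄)n₃ + k₋₄n₄
dn₄/dt =  k₄n₃ − k₋₄n₄
```

The PM→RE→LM→PM circuit cycles sterol between the cell surface and
endo-lysosomes; the bidirectional LM↔ILV exchange (k₄, k₋₄) maps the
activity of the luminal transfer protein NPC2. Variants:

* **closed_three** — k₄ = k₋₄ = 0; sufficient for control cells.
* **closed_four** — the full closed cycle; the slow ILV exchange produces
  the biphasic endo-lysosomal accumulation seen in NPC2-deficient
  ("disease") cells during pulse-chase experiments.
* **open_four** — adds constant influx *v*₀ into the PM and first-order PM
  efflux k₅ (continuous-uptake experiments). Its steady-state *fractions*
  are independent of *v*₀ and k₅ and proportional to
  (k₃/k₁, k₃/k₂, 1, q₂) with **q₂ = k₄/k₋₄**; the intracellular fraction is
  (k₃/k₂ + 1 + q₂)/(k₃/k₁ + k₃/k₂ + 1 + q₂).
* **efflux_two_pathway** — no influx; efflux from the PM (pathway I:
  ectosome shedding / transfer to ApoA1, rate k₅) and directly from the
  ILVs by lysosomal exocytosis of exosomes (pathway II) with the
  time-dependent Weibull rate coefficient **k(t) = μ·k₆^μ·t^(μ−1)**,
  k₆ = 1/τ. For μ > 1 (compressed exponential) export is delayed and then
  accelerates; μ = 1 recovers a constant rate.

Efflux measurements are summarised by the offset Weibull survival law
F(t) = f∞ + (f₀ − f∞)·exp(−(t/τ)^μ), fitted by `fit_weibull_efflux`.
Model parameters are estimated by global weighted least squares across all
series of all experiments simultaneously (`global_fit`), with
Jacobian-based standard deviations and AIC/BIC model comparison
(`compare_models`). A synthetic-data module generates pulse-chase,
continuous-uptake and efflux datasets with additive Gaussian noise for
recovery and model-selection studies.

## Worked example

```python
from sterolflux import DISEASE_PARAMS, intracellular_fraction, transit_time
print(f"{intracellular_fraction(DISEASE_PARAMS):.4f}")   # 0.3961
print(f"{transit_time(DISEASE_PARAMS):.2f} min")         # 39.14 min
```

The first number is the steady-state fraction of cellular sterol held in
RE + LM + ILV for the disease-cell rate constants
(k₁ = 0.03216, k₂ = 0.4331, k₃ = 0.1744, k₄ = 0.0084, k₋₄ = 0.0039 min⁻¹):
about 40% of the tracer accumulates inside the cell, mostly in ILVs
(q₂ ≈ 2.15). The second is the PM→RE→LM→PM transit time
1/k₁ + 1/k₂ + 1/k₃ ≈ 39 min — sterol cycling through the limiting membrane
is *fast* in disease cells (control: ≈ 98 min); the storage phenotype comes
from ILV trapping, not from slow export out of the endo-lysosomal membrane.

Narrative scripts in `examples/` cover each capability (steady-state
analysis and the q₂ sweep, pulse-chase simulation, two-pathway efflux,
global fitting, BIC model selection); each prints the numbers it computes
with a line on what they mean. A thin CLI mirrors the library:

```bash
sterolflux steady-state --preset disease
sterolflux generate --experiment pulse-chase --preset disease --seed 5 --out pc.csv
sterolflux fit --data pc.csv --variant closed_four --out-prefix fit
```

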