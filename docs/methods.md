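# Methods

## Model structure and assumptions

Sterol transport is modelled as a linear compartment system over four
well-mixed pools: plasma membrane (PM, n₁), recycling endosomes (RE, n₂),
the limiting membrane of late endosomes/lysosomes (LM, n₃) and the
intraluminal vesicles (ILV, n₄). Amounts are in arbitrary fluorescence
units — fluorescence of the tracer is taken proportional to sterol amount
per pool, so rate constants are first order (min⁻¹) and no compartment
volumes are needed. Transport around the PM→RE→LM→PM circuit is
unidirectional; overall PM↔endo-lysosome exchange is still reversible
because the circuit closes. LM↔ILV exchange is bidirectional with rates k₄
and k₋₄; their ratio q₂ = k₄/k₋₄ is the equilibrium constant of
intraluminal sterol partitioning and the model's handle on NPC2 transfer
activity. Excluded on purpose: ER/TGN/mitochondrial pools and sterol
esterification (quantitatively minor for PM-derived sterol in fibroblasts),
homeostatic feedback and de novo synthesis (the efflux model describes
transient export kinetics only), and any spatial or single-particle
structure (all pools are assumed rapidly mixed).

The two-pathway efflux variant removes sterol (i) from the PM at constant
rate k₅ (ectosome shedding and/or transfer to extracellular acceptors) and
(ii) directly from the ILV pool by lysosomal exocytosis with the
time-dependent coefficient k(t) = μ·k₆^μ·t^(μ−1) — the hazard of the
Weibull survival law S(t) = exp(−(t/τ)^μ) with k₆ = 1/τ. The full
supplementary form of the efflux equations was not available in the source
text; the equations used here are a reconstruction from the narrative
description and are flagged as such: pathway II drains n₄ only (ILVs are
the exosome precursors), with dn₄/dt = k₄n₃ − k₋₄n₄ − k(t)·n₄ and the PM
balance dn₁/dt = −(k₁+k₅)n₁ + k₃n₃. For μ > 1 the hazard vanishes at t = 0
and is extended there by continuity, so simulations start exactly at the
experiment origin; for μ = 1 the variant reduces exactly to a
constant-coefficient system with ILV export rate k₆ (verified against the
matrix-exponential solution). A `reversible_two_branch` comparison variant
(independent PM↔RE and PM↔LE/LYS branches) exists only for
model-comparison demonstrations; its exact rate structure is an
interpretation, as no canonical form was available.

## Parameters

| symbol | meaning | unit | disease preset | control preset |
|---|---|---|---|---|
| k₁ | PM → RE | min⁻¹ | 0.03216 | 0.01204 |
| k₂ | RE → LM | min⁻¹ | 0.4331 | 0.2465 |
| k₃ | LM → PM | min⁻¹ | 0.1744 | 0.09351 |
| k₄ | LM → ILV | min⁻¹ | 0.0084 | — (0.01686 with restored exchange) |
| k₋₄ | ILV → LM | min⁻¹ | 0.0039 | — (0.0843, giving q₂ = 0.2) |
| v₀ | influx into PM | amount·min⁻¹ | scenario-dependent | |
| k₅ | PM efflux | min⁻¹ | 10⁻⁴–10⁻³ in efflux scenarios | |
| k₆ | 1/τ, exocytosis time scale | min⁻¹ | 0.0015 | |
| μ | Weibull shape | — | 2.577 (1.324 after NPC2 treatment) | |

All internal times are minutes; hour-valued inputs (efflux grids, τ) are
converted on ingest and only at the presentation layer converted back. A
conflicting k₆ statement in units of s⁻¹ exists in the source narrative;
the min⁻¹ figure used in the simulation legends (0.0015 min⁻¹) is taken as
authoritative. Parameter validation rejects negative rates rather than
clipping, because fitted first-order constants are physical quantities.

## Steady state

With influx and PM efflux the system is open and relaxes to
n₁* = v₀/k₅, n₃* = v₀k₁/(k₃k₅), n₂* = (k₃/k₂)n₃*, n₄* = q₂n₃*. The
compartment *fractions* are therefore proportional to
(k₃/k₁, k₃/k₂, 1, q₂) — independent of v₀ and k₅ — and the intracellular
fraction is (k₃/k₂ + 1 + q₂)/(k₃/k₁ + k₃/k₂ + 1 + q₂). These closed forms
are verified symbolically in the test suite (sympy solves the linear
steady-state system and the expressions are compared term by term) and
numerically (the integrated open system reproduces them, and the closed
system relaxes to the same fractional split). The q₂ sweep holds k₋₄ fixed
and varies k₄; since the fraction depends on the exchange rates only
through their ratio, this reproduces any parametrisation by q₂ alone. The
intracellular fraction is strictly increasing in q₂ (hyperbolic saturation
below 1) and strictly increasing in k₁ (the PM-trapping limit k₁ → 0 sends
it to 0). The overall transit time of the surface circuit is
1/k₁ + 1/k₂ + 1/k₃ (≈ 39 min for the disease preset, ≈ 98 min for
control). Fractions are reported to 4 decimals in summaries.

## Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA at rtol 1e−8 /
atol 1e−10. The rates span ≈ 0.004–0.43 min⁻¹, so stiffness is mild, but
the Weibull hazard grows without bound for μ > 1, which motivates adaptive
stepping. Closed variants conserve the total to better than 1e−8 over the
simulated windows; solver output may carry negatives of order atol, which
are clamped to zero in derived observables only. For every
constant-coefficient variant an exact propagator via the matrix exponential
of the augmented system [[A, b], [0, 0]] is available
(`propagate_linear`); it doubles as an independent cross-check of the
adaptive integrator (agreement ≤ 1e−7 on random instances) and as the model
evaluator inside fitting, where a parameter-smooth response is essential:
finite-difference Jacobians over an adaptive solver inherit step-selection
noise, which in the nearly flat likelihood valley of sparsely sampled
pulse-chase designs stalls the optimiser far from the optimum.

Efflux simulations default to the loading steady state: the open-system
fractions normalised to total 1. Whether the original efflux simulations
used exact steady-state or finite-loading-time initial fractions is not
stated in the source; steady-state fractions are used here. The source
narrative also contains an internally inconsistent plateau time for the
efflux fraction ("200 h, corresponding to 1,200 min"); the simulation
itself is the arbiter — with the disease parameters the endo-lysosomal
fraction plateaus on the 150–200 h scale (200 h = 12,000 min).

## Fitting

`global_fit` minimises the pooled weighted least-squares objective over all
series of all supplied datasets with one shared parameter vector
(weights 1/sd² when per-point uncertainties are present, uniform
otherwise — uncertainties for the original measurements are not published,
so uniform is the default). The optimiser is bounded
trust-region-reflective `scipy.optimize.least_squares` with optional
multi-start: additional starts perturb the initial guess by log-uniform
factors in [0.2, 5] and the best final cost wins; the perturbation seed is
recorded in the result. Standard deviations come from the covariance
RSS/(n−p)·(JᵀJ)⁻¹ at the optimum; the coefficient of variation is reported
as sd/estimate (the printed CVs of the original parameter table do not all
equal sd/mean exactly, suggesting the original software used a slightly
different convention; sd/estimate is used consistently here). Parameters
with CV > 10, or a singular JᵀJ, attach a non-identifiability warning —
e.g. requesting k₄, k₋₄ on single-phase control-like data. Control-style
fits use the three-compartment variant (k₄ = k₋₄ = 0), since single-phase
data cannot constrain the ILV exchange. The LE/LYS observable is always
fitted as n₃ + n₄; the sub-pools are never fitted separately because they
are optically inseparable.

Model comparison uses the Gaussian least-squares forms
AIC = n·ln(RSS/n) + 2p and BIC = n·ln(RSS/n) + p·ln n, ranked by BIC with
AIC as tie-break; RSS = 0 (perfect interpolation) is flagged degenerate.
The offset-Weibull efflux fit estimates (τ, μ, f₀, f∞) in
F(t) = f∞ + (f₀−f∞)exp(−(t/τ)^μ) by the same bounded least squares, with
μ optionally fixed; it is scale-consistent (rescaling time rescales τ,
leaves μ unchanged) and requires at least five points and a non-flat
series.

## Synthetic data

The generators stand in for the (undeposited) fluorescence measurements.
They emulate: pulse-chase (all tracer in the PM at t = 0, fractions of a
unit pool, default grid 0–120 min at 10 points), continuous uptake (open
system from an empty cell, approach to the analytic steady state) and
efflux (default grid {0, 24, 48, 72, 96} h, mirroring daily sampling up to
96 h; the exact grids and replicate counts of the original experiments are
not published, so these are stated stand-ins). Noise is additive Gaussian
on the fractional signal, σ = 0.02 fraction units by default, clipped at
zero — chosen so that recovery CVs are comparable to the 0.1–0.4 range
reported for the experimental fits; a proportional-Gaussian option exists.
Generation is bit-reproducible given the seed, and every dataset carries a
provenance block (truth parameters, grid, noise, seed) that the CSV writer
emits as `#` comments.

What the generators do *not* emulate: photobleaching, segmentation error,
point-spread blur, cell-to-cell heterogeneity, or correlated residuals.
Passing recovery tests therefore demonstrates the estimator's correctness
and precision under the stated noise model, not robustness to the full
error structure of microscopy data.

## Study designs used in the recovery tests

Sampling density matters: on a uniform 0–360 min grid at 13 points the
fast surface-circuit rates (time scales 2–6 min) are barely resolved and
the likelihood has a long, flat valley along a joint rescaling of
k₁–k₃ — with 2% noise those rates are then practically non-identifiable.
The Monte-Carlo recovery study therefore uses a dense-early design
(0–480 min, 17 points, spacing growing from 2 to 60 min), the standard
layout for a pulse-chase experiment with fast initial redistribution and a
slow late phase; on it, 100 replicates at 2% noise recover all five
disease rates with < 5% mean bias and CVs ≤ 0.27. Model selection by BIC
(100 replicates, 2% noise, uniform 13-point grid, three-pool vs four-pool)
identifies the generating variant in ≥ 90% of replicates. The
offset-Weibull study uses 200 replicates at 1% noise on the daily efflux
grid; the median recovered τ stays within 5% of truth. These problem sizes
were chosen once as desk-scale defaults that make the sampling error of
the Monte-Carlo summaries small relative to the tested tolerances.

## Known limitations

* ILV kinetics are parametrised indirectly (only n₃ + n₄ is observable),
  so k₄/k₋₄ inherit the largest uncertainties.
* The efflux equations are a reconstruction (see above); alternative delay
  mechanisms (Erlang chains, stretched-exponential export) are not
  implemented.
* No Bayesian posterior or profile-likelihood machinery — identifiability
  is flagged heuristically via CVs and Jacobian rank only.
* The steady-state analysis assumes strictly positive cycle rates; zero
  rates raise singularity errors rather than returning limits.
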