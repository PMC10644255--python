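"""Steady-state analysis of the open sterol-transport system.

Computes the analytic steady state for disease-cell (NPC2-deficient) and
control rate constants: compartment fractions, the intracellular sterol
fraction, the ILV<->LM equilibrium constant q2 and the PM->RE->LM->PM
transit time.  The intracellular fraction is independent of the influx and
efflux rates, so it is directly comparable to continuous-uptake experiments.
"""

import numpy as np

from sterolflux import (
    CONTROL_PARAMS,
    DISEASE_PARAMS,
    fraction_vs_q2,
    intracellular_fraction,
    steady_state_summary,
    transit_time,
)

for label, params in (("disease", DISEASE_PARAMS), ("control", CONTROL_PARAMS)):
    summary = steady_state_summary(params).iloc[0]
    print(f"{label} cells:")
    print(f"  intracellular fraction (RE+LM+ILV)/total = {summary['intracellular_fraction']:.4f}")
    print(f"  transit time 1/k1 + 1/k2 + 1/k3          = {summary['transit_time_min']:.2f} min")
    print(f"  q2 = k4/k-4                              = {summary['q2']:.4f}")

# How the intracellular fraction responds to the ILV<->LM equilibrium: sterol
# accumulates hyperbolically as transfer out of the ILVs becomes impaired.
sweep = fraction_vs_q2(DISEASE_PARAMS, np.array([0.0, 0.2, 0.5, 1.0, 2.1538, 5.0, 20.0]))
print("\nintracellular fraction vs q2 (disease k1-k3):")
print(sweep.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
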