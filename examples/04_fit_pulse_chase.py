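"""Global fitting: recover rate constants from noisy pulse-chase curves.

Generates a synthetic pulse-chase dataset from the disease-cell rate
constants with 2% additive measurement noise on a dense-early sampling
design, then refits all five rates globally (one parameter vector against
PM, RE and LE/LYS curves simultaneously) and prints the estimates with
their Jacobian-based standard deviations and coefficients of variation.
"""

import numpy as np

from sterolflux import DISEASE_PARAMS, NoiseSpec, generate_pulse_chase, global_fit

grid = np.array([0, 2, 5, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240, 300, 360, 420, 480.0])
dataset = generate_pulse_chase(
    DISEASE_PARAMS, grid=grid, noise=NoiseSpec(sigma=0.02, seed=11)
)
result = global_fit(dataset, "closed_four", n_starts=5, seed=0)

truth = {"k1": 0.03216, "k2": 0.4331, "k3": 0.1744, "k4": 0.0084, "km4": 0.0039}
print("parameter   truth     estimate        sd      cv")
for name, true_value in truth.items():
    print(
        f"{name:>6} {true_value:10.5f} {result.estimates[name]:10.5f} "
        f"{result.sd[name]:10.5f} {result.cv[name]:7.3f}"
    )
print(f"\nRSS = {result.rss:.4g} on {result.n_obs} points, "
      f"AIC = {result.aic:.1f}, BIC = {result.bic:.1f}, converged = {result.converged}")
print("CVs of a few percent up to ~0.3 mirror the precision attainable from"
      " fractional-fluorescence time courses at this noise level.")
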