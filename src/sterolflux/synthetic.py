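"""Synthetic fluorescence time courses for recovery and model-selection studies.

The generators emulate the three experiment designs the model is fitted to:

* **pulse-chase** — brief PM labelling, closed system, fractions of a unit
  tracer pool followed over ~2 h (default grid 0–120 min, 10 points);
* **continuous uptake** — constant influx from an extracellular donor,
  approach to the open-system steady state;
* **efflux** — decline of the intracellular fraction after removal of the
  sterol source, either from the offset-Weibull law directly or from the
  mechanistic two-pathway model (default grid {0, 24, 48, 72, 96} h).

Measurement error is modelled as additive (or proportional) Gaussian noise
on the fractional fluorescence, sigma = 0.02 fraction units by default,
clipped at zero.  Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TimeCourseDataset, TimeSeries
from .errors import ParameterError
from .models import CompartmentState, RateConstants, get_variant, weibull_survival
from .simulation import ScenarioSpec, integrate

__all__ = [
    "NoiseSpec",
    "WeibullTruth",
    "generate_pulse_chase",
    "generate_continuous_uptake",
    "generate_efflux",
    "DEFAULT_PULSE_CHASE_GRID",
    "DEFAULT_EFFLUX_GRID_H",
]

#: Experimental-style sampling grids: pulse-chase 0–120 min at 10 points,
#: efflux at five daily time points up to 96 h.
DEFAULT_PULSE_CHASE_GRID = np.linspace(0.0, 120.0, 10)
DEFAULT_EFFLUX_GRID_H = np.array([0.0, 24.0, 48.0, 72.0, 96.0])


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for generated fractional-fluorescence data."""

    kind: str = "additive_gaussian"
    sigma: float = 0.02
    seed: int = 0
    clip_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "proportional_gaussian"):
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ParameterError(f"'sigma' must be >= 0, got {self.sigma!r}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Add one noise realisation; exact pass-through when sigma = 0."""
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        draw = rng.normal(0.0, self.sigma, size=values.shape)
        noisy = values + draw if self.kind == "additive_gaussian" else values * (1.0 + draw)
        return np.clip(noisy, 0.0, None) if self.clip_at_zero else noisy


@dataclass(frozen=True)
class WeibullTruth:
    """Ground-truth offset-Weibull efflux law (tau in hours)."""

    tau_h: float
    mu: float
    f0: float
    f_inf: float

    def __post_init__(self) -> None:
        if self.tau_h <= 0 or self.mu <= 0:
            raise ParameterError("'tau_h' and 'mu' must be > 0")
        if not self.f0 > self.f_inf >= 0:
            raise ParameterError(
                f"need f0 > f_inf >= 0, got f0={self.f0!r}, f_inf={self.f_inf!r}"
            )


def _check_grid(grid: np.ndarray, start_at_zero: bool = True) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ParameterError("grid must be a strictly increasing 1-D sequence, t >= 0")
    if start_at_zero and grid[0] != 0:
        raise ParameterError("grid must start at 0")
    return grid


def _provenance(kind: str, params, grid: np.ndarray, noise: NoiseSpec) -> dict:
    truth = params.as_dict() if hasattr(params, "as_dict") else dict(params.__dict__)
    return {
        "generator": kind,
        "truth": truth,
        "grid": list(np.round(grid, 10)),
        "noise_kind": noise.kind,
        "noise_sigma": noise.sigma,
        "seed": noise.seed,
    }


def generate_pulse_chase(
    params: RateConstants,
    variant: str = "closed_four",
    grid: "np.ndarray | None" = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    cell_line: str = "synthetic",
) -> TimeCourseDataset:
    """Noisy PM/RE/LELY fractions from a closed-system pulse-chase simulation."""
    var = get_variant(variant)
    if not var.closed:
        raise ParameterError(f"pulse-chase requires a closed variant, got {var.name!r}")
    grid = _check_grid(DEFAULT_PULSE_CHASE_GRID if grid is None else grid)
    spec = ScenarioSpec(
        variant=var,
        params=params,
        initial_state=CompartmentState(n1=1.0),
        t_end=float(grid[-1]),
        label=cell_line,
    )
    traj = integrate(spec, t_eval=grid)
    rng = np.random.default_rng(noise.seed)
    series = {
        name: TimeSeries(time=grid, value=noise.apply(traj.observable(name), rng))
        for name in ("PM", "RE", "LELY")
    }
    return TimeCourseDataset(
        cell_line=cell_line,
        experiment="pulse_chase",
        series=series,
        provenance=_provenance(f"pulse_chase/{var.name}", params, grid, noise),
    )


def generate_continuous_uptake(
    params: RateConstants,
    grid: np.ndarray,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    cell_line: str = "synthetic",
) -> TimeCourseDataset:
    """Noisy uptake curves of the open system started from an empty cell."""
    if params.v0 <= 0:
        raise ParameterError("'v0' must be > 0 for a continuous-uptake experiment")
    grid = _check_grid(grid)
    spec = ScenarioSpec(
        variant="open_four",
        params=params,
        initial_state=CompartmentState(),
        t_end=float(grid[-1]),
        label=cell_line,
    )
    traj = integrate(spec, t_eval=grid)
    rng = np.random.default_rng(noise.seed)
    series = {
        name: TimeSeries(time=grid, value=noise.apply(traj.observable(name), rng))
        for name in ("PM", "RE", "LELY")
    }
    return TimeCourseDataset(
        cell_line=cell_line,
        experiment="continuous_uptake",
        series=series,
        provenance=_provenance("continuous_uptake/open_four", params, grid, noise),
    )


def generate_efflux(
    source: "WeibullTruth | RateConstants",
    grid_h: "np.ndarray | None" = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    cell_line: str = "synthetic",
) -> TimeCourseDataset:
    """Noisy efflux decay, from a Weibull law or the mechanistic model.

    ``grid_h`` is in hours (the natural unit of efflux experiments); the
    dataset stores minutes.  With a :class:`WeibullTruth` source the single
    emitted series is the intracellular fraction
    F(t) = f_inf + (f0 - f_inf) S(t); with a :class:`RateConstants` source
    the two-pathway model is simulated from its loading steady state and
    PM/RE/LELY plus the intracellular fraction are emitted.
    """
    grid_h = _check_grid(DEFAULT_EFFLUX_GRID_H if grid_h is None else grid_h)
    if grid_h[-1] > 220.0:
        raise ParameterError("efflux grids beyond ~200 h are not supported")
    grid_min = grid_h * 60.0
    rng = np.random.default_rng(noise.seed)
    if isinstance(source, WeibullTruth):
        clean = source.f_inf + (source.f0 - source.f_inf) * weibull_survival(
            grid_h, source.tau_h, source.mu
        )
        series = {
            "intracellular_fraction": TimeSeries(
                time=grid_min, value=noise.apply(clean, rng)
            )
        }
        label = "efflux/weibull"
    elif isinstance(source, RateConstants):
        spec = ScenarioSpec(
            variant="efflux_two_pathway",
            params=source,
            initial_state="steady_fractions",
            t_end=float(grid_min[-1]),
            label=cell_line,
        )
        traj = integrate(spec, t_eval=grid_min)
        series = {
            name: TimeSeries(time=grid_min, value=noise.apply(traj.observable(name), rng))
            for name in ("PM", "RE", "LELY")
        }
        series["intracellular_fraction"] = TimeSeries(
            time=grid_min, value=noise.apply(traj.lely_fraction, rng)
        )
        label = "efflux/two_pathway"
    else:
        raise ParameterError(
            "source must be a WeibullTruth or RateConstants, "
            f"got {type(source).__name__}"
        )
    return TimeCourseDataset(
        cell_line=cell_line,
        experiment="efflux",
        series=series,
        provenance=_provenance(label, source, grid_h, noise),
    )
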