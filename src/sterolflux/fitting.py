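"""Global nonlinear regression of transport models to time-course data.

Model parameters are estimated *globally*: one parameter vector is optimised
against all series of all supplied datasets simultaneously, minimising the
pooled weighted least-squares objective

    RSS(theta) = sum_series sum_i w_i * (y_i - y_model(t_i; theta))**2

with weights w_i = 1/sd_i**2 when per-point uncertainties are given and 1
otherwise.  Optimisation uses bounded trust-region-reflective least squares
with optional multi-start (log-uniform perturbations of the initial guess);
parameter standard deviations come from the Jacobian-based covariance at the
optimum.  Model comparison uses the Gaussian-likelihood information criteria

    AIC = n ln(RSS/n) + 2 p,      BIC = n ln(RSS/n) + p ln n.

The offset Weibull fit for efflux curves estimates (tau, mu, f0, f_inf) in

    F(t) = f_inf + (f0 - f_inf) * exp(-(t/tau)**mu),

the survival function weighted by the initial fractional intensity f0 with
an offset f_inf for the remnant at steady state.
"""

from __future__ import annotations

import math
import warnings as _pywarnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import TimeCourseDataset, TimeSeries
from .errors import (
    DegenerateFitError,
    NonIdentifiableError,
    ParameterError,
    SterolFluxError,
)
from .models import CompartmentState, ModelVariant, RateConstants, get_variant
from .simulation import ScenarioSpec, integrate, propagate_linear
from .steady_state import steady_state_fractions

__all__ = [
    "FitResult",
    "WeibullFit",
    "global_fit",
    "fit_weibull_efflux",
    "information_criteria",
    "compare_models",
]

# Default box constraints per free parameter (min^-1 for rates).
_DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "k1": (1e-6, 10.0),
    "k2": (1e-6, 10.0),
    "k3": (1e-6, 10.0),
    "k4": (1e-6, 10.0),
    "km4": (1e-6, 10.0),
    "v0": (1e-6, 100.0),
    "k5": (1e-8, 10.0),
    "k6": (1e-8, 10.0),
    "mu": (0.1, 10.0),
}
_DEFAULT_GUESS: Mapping[str, float] = {
    "k1": 0.05,
    "k2": 0.3,
    "k3": 0.1,
    "k4": 0.01,
    "km4": 0.01,
    "v0": 1.0,
    "k5": 1e-3,
    "k6": 1e-3,
    "mu": 1.5,
}


def information_criteria(rss: float, n_obs: int, n_params: int) -> tuple[float, float]:
    """Gaussian-likelihood AIC and BIC from a least-squares fit."""
    if n_obs <= n_params:
        raise ParameterError(
            f"need n_obs > n_params, got n_obs={n_obs}, n_params={n_params}"
        )
    if rss <= 0:
        raise DegenerateFitError(
            "information criteria undefined at RSS <= 0 (perfect interpolation)"
        )
    base = n_obs * math.log(rss / n_obs)
    return base + 2 * n_params, base + n_params * math.log(n_obs)


@dataclass(frozen=True)
class FitResult:
    """Point estimates and uncertainty summary of one global fit."""

    variant: ModelVariant
    estimates: dict[str, float]
    sd: dict[str, float]
    cv: dict[str, float]  # sd/estimate, the convention used in fit reports
    rss: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    converged: bool
    seed: "int | None" = None
    warnings: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        """Per-parameter report (parameter, estimate, sd, cv)."""
        return pd.DataFrame(
            {
                "parameter": list(self.estimates),
                "estimate": list(self.estimates.values()),
                "sd": [self.sd[k] for k in self.estimates],
                "cv": [self.cv[k] for k in self.estimates],
            }
        )

    def summary(self) -> dict:
        """Structured summary for JSON-style export."""
        return {
            "variant": self.variant.name,
            "estimates": dict(self.estimates),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


_EFFLUX_OBSERVABLE_MAP = {"intracellular_fraction": "LELY_fraction"}


def _observable_name(experiment: str, series_name: str) -> str:
    # In efflux experiments the measured "intracellular" signal is the
    # endo-lysosomal share (n3 + n4)/total.
    if experiment == "efflux":
        return _EFFLUX_OBSERVABLE_MAP.get(series_name, series_name)
    return series_name


def _initial_state(dataset: TimeCourseDataset, params: RateConstants):
    if dataset.experiment == "pulse_chase":
        return CompartmentState(n1=1.0)
    if dataset.experiment == "continuous_uptake":
        return CompartmentState()
    # efflux: loading steady state normalised to total 1
    return CompartmentState.from_array(steady_state_fractions(params))


def _predict_dataset(
    dataset: TimeCourseDataset,
    variant: ModelVariant,
    params: RateConstants,
    rtol: float,
    atol: float,
) -> dict[str, np.ndarray]:
    """Model value for every series of one dataset at its own time points."""
    grid = np.unique(np.concatenate([s.time for s in dataset.series.values()]))
    t_end = float(grid[-1]) if grid[-1] > 0 else 1.0
    init = _initial_state(dataset, params)
    if not variant.time_dependent or params.mu == 1.0:
        # Exact, parameter-smooth evaluation: essential for the
        # finite-difference Jacobian in a nearly flat likelihood valley.
        traj = propagate_linear(variant, params, init, grid, label=dataset.cell_line)
    else:
        spec = ScenarioSpec(
            variant=variant,
            params=params,
            initial_state=init,
            t_end=t_end,
            n_points=2,
            label=dataset.cell_line,
        )
        traj = integrate(spec, rtol=rtol, atol=atol, t_eval=grid)
    out: dict[str, np.ndarray] = {}
    for name, series in dataset.series.items():
        values = traj.observable(_observable_name(dataset.experiment, name))
        idx = np.searchsorted(grid, series.time)
        out[name] = values[idx]
    return out


def _residuals(
    theta: np.ndarray,
    free: Sequence[str],
    base: RateConstants,
    datasets: Sequence[TimeCourseDataset],
    variant: ModelVariant,
    rtol: float,
    atol: float,
) -> np.ndarray:
    params = base.replace(**dict(zip(free, theta)))
    chunks: list[np.ndarray] = []
    for dataset in datasets:
        predicted = _predict_dataset(dataset, variant, params, rtol, atol)
        for name, series in dataset.series.items():
            res = predicted[name] - series.value
            if series.sd is not None:
                res = res / series.sd
            chunks.append(res)
    return np.concatenate(chunks)


def global_fit(
    datasets: "TimeCourseDataset | Iterable[TimeCourseDataset]",
    variant: "str | ModelVariant",
    free_params: "Sequence[str] | None" = None,
    initial_guess: "Mapping[str, float] | None" = None,
    bounds: "Mapping[str, tuple[float, float]] | None" = None,
    base_params: "RateConstants | None" = None,
    n_starts: int = 10,
    seed: "int | None" = 0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Fit one parameter vector to all series of all datasets simultaneously.

    Parameters
    ----------
    datasets
        One or more :class:`TimeCourseDataset`; all are fitted jointly.
    variant
        Model variant name or object; its active parameters define the
        default free set.
    free_params
        Names of parameters to optimise (default: the variant's active set).
    initial_guess, bounds
        Optional per-parameter overrides of the defaults.
    base_params
        Values for parameters held fixed (default: all zero, mu = 1).
    n_starts
        Multi-start count; starts beyond the first perturb the guess by
        log-uniform factors in [0.2, 5] and the best final cost is kept.
    seed
        Seed for the perturbation RNG, recorded in the result.
    """
    if isinstance(datasets, TimeCourseDataset):
        datasets = [datasets]
    datasets = list(datasets)
    if not datasets:
        raise ParameterError("global_fit requires at least one dataset")
    var = get_variant(variant)
    free = sorted(var.active_parameters) if free_params is None else list(free_params)
    for name in free:
        if name not in var.active_parameters:
            raise ParameterError(
                f"parameter {name!r} is not active in variant {var.name!r}"
            )
    base = base_params if base_params is not None else RateConstants()

    guess_map = dict(_DEFAULT_GUESS)
    if initial_guess:
        guess_map.update(initial_guess)
    bounds_map = dict(_DEFAULT_BOUNDS)
    if bounds:
        bounds_map.update(bounds)
    lo = np.array([bounds_map[p][0] for p in free])
    hi = np.array([bounds_map[p][1] for p in free])
    x0 = np.clip(np.array([guess_map[p] for p in free]), lo, hi)

    rng = np.random.default_rng(seed)
    n_obs = sum(d.n_obs for d in datasets)
    if n_obs <= len(free):
        raise ParameterError(
            f"not enough observations ({n_obs}) for {len(free)} free parameters"
        )

    args = (free, base, datasets, var, rtol, atol)
    best = None
    for start in range(max(1, n_starts)):
        x_start = x0 if start == 0 else np.clip(
            x0 * np.exp(rng.uniform(np.log(0.2), np.log(5.0), size=x0.size)), lo, hi
        )
        try:
            res = least_squares(
                _residuals,
                x_start,
                bounds=(lo, hi),
                args=args,
                method="trf",
                x_scale="jac",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
            )
        except SterolFluxError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise NonIdentifiableError("all optimisation starts failed")

    rss = float(2.0 * best.cost)
    estimates = dict(zip(free, (float(v) for v in best.x)))
    n_params = len(free)
    fit_warnings: list[str] = []

    # Jacobian-based covariance at the optimum.
    sd_map = {p: float("nan") for p in free}
    if n_obs > n_params and rss > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (n_obs - n_params)
            sd_vals = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            sd_map = dict(zip(free, (float(v) for v in sd_vals)))
        except np.linalg.LinAlgError:
            fit_warnings.append(
                "singular Jacobian at the optimum: parameters are structurally "
                "non-identifiable from these data"
            )
    cv_map = {
        p: (sd_map[p] / estimates[p] if estimates[p] != 0 else float("nan"))
        for p in free
    }
    for p in free:
        if math.isfinite(cv_map[p]) and cv_map[p] > 10:
            fit_warnings.append(
                f"parameter {p!r} is practically non-identifiable (CV = {cv_map[p]:.1f})"
            )
    try:
        aic, bic = information_criteria(rss, n_obs, n_params)
    except DegenerateFitError:
        aic = bic = float("-inf")
        fit_warnings.append("RSS = 0: information criteria degenerate")
    return FitResult(
        variant=var,
        estimates=estimates,
        sd=sd_map,
        cv=cv_map,
        rss=rss,
        n_obs=n_obs,
        n_params=n_params,
        aic=aic,
        bic=bic,
        converged=bool(best.status > 0),
        seed=seed,
        warnings=tuple(fit_warnings),
    )


@dataclass(frozen=True)
class WeibullFit:
    """Offset-Weibull efflux fit F(t) = f_inf + (f0 - f_inf) exp(-(t/tau)^mu)."""

    tau: float
    mu: float
    f0: float
    f_inf: float
    rss: float
    sd: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __call__(self, t) -> np.ndarray:
        t_arr = np.asarray(t, dtype=float)
        return self.f_inf + (self.f0 - self.f_inf) * np.exp(
            -((t_arr / self.tau) ** self.mu)
        )


def fit_weibull_efflux(
    series: "TimeSeries | tuple",
    initial_guess: "Mapping[str, float] | None" = None,
    fix_mu: "float | None" = None,
) -> WeibullFit:
    """Fit the offset Weibull decay to an efflux series (times, fractions).

    ``series`` is either a :class:`TimeSeries` or a (time, value) pair; the
    time unit is preserved (tau comes out in the same unit).  ``fix_mu``
    pins the shape parameter (mu = 1 gives an exponential-with-offset fit).
    """
    if isinstance(series, TimeSeries):
        t, y, sd = series.time, series.value, series.sd
    else:
        t, y = np.asarray(series[0], dtype=float), np.asarray(series[1], dtype=float)
        sd = None
    if t.size < 5:
        raise ParameterError(f"need >= 5 points to fit the offset Weibull, got {t.size}")
    if np.any(y < 0) or np.any(y > 1):
        raise ParameterError("efflux fractions must lie in [0, 1]")
    if float(np.ptp(y)) < 1e-12:
        raise NonIdentifiableError("series is flat: tau and mu are not identifiable")

    guess = {
        "f0": float(y[0]),
        "f_inf": max(float(y.min()) * 0.8, 1e-6),
        "tau": float(t[-1]) / 2.0 if t[-1] > 0 else 1.0,
        "mu": 1.5,
    }
    if initial_guess:
        guess.update(initial_guess)

    names = ["tau", "f0", "f_inf"] if fix_mu is not None else ["tau", "mu", "f0", "f_inf"]
    lo_map = {"tau": 1e-8, "mu": 1e-3, "f0": 0.0, "f_inf": 0.0}
    hi_map = {"tau": np.inf, "mu": 50.0, "f0": 2.0, "f_inf": 1.0}
    x0 = np.clip(
        [guess[n] for n in names], [lo_map[n] for n in names], [hi_map[n] for n in names]
    )

    def unpack(theta):
        vals = dict(zip(names, theta))
        if fix_mu is not None:
            vals["mu"] = fix_mu
        return vals

    def residuals(theta):
        v = unpack(theta)
        model = v["f_inf"] + (v["f0"] - v["f_inf"]) * np.exp(
            -((t / v["tau"]) ** v["mu"])
        )
        res = model - y
        return res / sd if sd is not None else res

    res = least_squares(
        residuals,
        x0,
        bounds=([lo_map[n] for n in names], [hi_map[n] for n in names]),
        method="trf",
        x_scale="jac",
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
    )
    vals = unpack(res.x)
    rss = float(2.0 * res.cost)
    sd_map: dict[str, float] = {}
    if t.size > len(names) and rss > 0:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (t.size - len(names))
            sd_map = dict(
                zip(names, (float(v) for v in np.sqrt(np.clip(np.diag(cov), 0, None))))
            )
        except np.linalg.LinAlgError:
            pass
    if not vals["f0"] > vals["f_inf"]:
        _pywarnings.warn(
            "fitted f0 <= f_inf: the series does not decay; estimates are suspect",
            stacklevel=2,
        )
    return WeibullFit(
        tau=float(vals["tau"]),
        mu=float(vals["mu"]),
        f0=float(vals["f0"]),
        f_inf=float(vals["f_inf"]),
        rss=rss,
        sd=sd_map,
        converged=bool(res.status > 0),
    )


def compare_models(
    datasets: "TimeCourseDataset | Iterable[TimeCourseDataset]",
    variants: Sequence["str | ModelVariant"],
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit several variants to the same data and rank them by BIC (ties: AIC).

    Returns the ranked comparison table (with Delta-criteria relative to the
    best model) and the underlying fit results; variants whose fit fails are
    reported as excluded rows with the failure reason.
    """
    if len(list(variants)) < 1:
        raise ParameterError("compare_models requires at least one variant")
    results: dict[str, FitResult] = {}
    rows: list[dict] = []
    for variant in variants:
        name = get_variant(variant).name
        try:
            fit = global_fit(datasets, variant, **fit_kwargs)
        except SterolFluxError as exc:
            rows.append(
                {"variant": name, "excluded": True, "reason": str(exc)}
            )
            continue
        results[name] = fit
        rows.append(
            {
                "variant": name,
                "excluded": False,
                "reason": "",
                "rss": fit.rss,
                "n_params": fit.n_params,
                "aic": fit.aic,
                "bic": fit.bic,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    fitted = table[~table["excluded"]].copy()
    if not fitted.empty:
        fitted = fitted.sort_values(["bic", "aic"], kind="stable")
        fitted["delta_bic"] = fitted["bic"] - fitted["bic"].iloc[0]
        fitted["delta_aic"] = fitted["aic"] - fitted["aic"].iloc[0]
        fitted["rank"] = np.arange(1, len(fitted) + 1)
        table = pd.concat(
            [fitted, table[table["excluded"]]], ignore_index=True
        )
    return table, results
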