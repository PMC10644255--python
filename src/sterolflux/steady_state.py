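"""Analytic steady state of the open four-compartment sterol transport model.

With constant influx v0 into the PM and first-order efflux k5 from the PM,
the linear system admits a unique attracting steady state obtained by setting
the RE, LM and ILV balances and the open PM balance to zero:

    n1* = v0 / k5
    n3* = v0 * k1 / (k3 * k5)
    n2* = (k3 / k2) * n3*
    n4* = q2 * n3*,        q2 = k4 / k-4

The *fractions* of total sterol per compartment depend only on the internal
rates — they are proportional to (k3/k1, k3/k2, 1, q2) — and are therefore
independent of the influx v0 and efflux k5.  The intracellular fraction

    f_ic = (k3/k2 + 1 + q2) / (k3/k1 + k3/k2 + 1 + q2)

is the model counterpart of the experimentally measured fraction of tracer
in REs + endo-lysosomes under continuous uptake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SingularityError
from .models import CompartmentState, RateConstants, get_variant

__all__ = [
    "SteadyStateResult",
    "steady_state_amounts",
    "steady_state_fractions",
    "intracellular_fraction",
    "q2_ratio",
    "fraction_vs_q2",
    "transit_time",
    "steady_state_summary",
]


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state amounts and derived fractions of the open system."""

    amounts: CompartmentState
    fractions: np.ndarray  # shares of total in PM, RE, LM, ILV; sums to 1
    intracellular_fraction: float
    q2: float


def _require_positive(params: RateConstants, names: Iterable[str]) -> None:
    for name in names:
        if getattr(params, name) <= 0:
            raise SingularityError(
                f"steady state undefined: rate {name!r} must be > 0, "
                f"got {getattr(params, name)!r}"
            )


def q2_ratio(k4: float, km4: float) -> float:
    """Equilibrium constant q2 = k4/k-4 for LM <-> ILV sterol exchange."""
    if k4 < 0 or km4 < 0:
        raise ParameterError("rates must be >= 0")
    if km4 == 0:
        if k4 == 0:
            return 0.0
        raise SingularityError("q2 undefined: 'km4' is 0 while 'k4' > 0")
    return k4 / km4


def _fraction_weights(params: RateConstants, q2: float | None = None) -> np.ndarray:
    """Unnormalised steady-state weights (k3/k1, k3/k2, 1, q2)."""
    _require_positive(params, ("k1", "k2", "k3"))
    if q2 is None:
        q2 = q2_ratio(params.k4, params.km4)
    return np.array([params.k3 / params.k1, params.k3 / params.k2, 1.0, q2])


def steady_state_fractions(params: RateConstants, q2: float | None = None) -> np.ndarray:
    """Steady-state fractional distribution over (PM, RE, LM, ILV).

    Depends only on k1, k2, k3 and q2 = k4/k-4; also the long-time
    fractional distribution of the closed variants.
    """
    w = _fraction_weights(params, q2)
    return w / w.sum()


def steady_state_amounts(params: RateConstants) -> SteadyStateResult:
    """Closed-form steady-state amounts of the open four-compartment model."""
    _require_positive(params, ("k1", "k2", "k3", "k5", "v0"))
    if params.k4 > 0 and params.km4 <= 0:
        raise SingularityError("steady state undefined: 'km4' is 0 while 'k4' > 0")
    q2 = q2_ratio(params.k4, params.km4)
    n3 = params.v0 * params.k1 / (params.k3 * params.k5)
    amounts = CompartmentState(
        n1=(params.k3 / params.k1) * n3,
        n2=(params.k3 / params.k2) * n3,
        n3=n3,
        n4=q2 * n3,
    )
    fractions = steady_state_fractions(params, q2)
    return SteadyStateResult(
        amounts=amounts,
        fractions=fractions,
        intracellular_fraction=float(fractions[1:].sum()),
        q2=q2,
    )


def intracellular_fraction(params: RateConstants, q2: float | None = None) -> float:
    """Steady-state fraction of sterol in RE + LM + ILV relative to total.

    Independent of v0 and k5; strictly increasing in q2 and decreasing in k1.
    """
    fractions = steady_state_fractions(params, q2)
    return float(fractions[1:].sum())


def fraction_vs_q2(params: RateConstants, q2_values: Sequence[float]) -> pd.DataFrame:
    """Sweep of the intracellular fraction over the LM<->ILV equilibrium q2.

    For each requested q2 the ratio k4/k-4 is forced to that value (k-4 held
    fixed, k4 varied) and the steady-state intracellular fraction evaluated.
    Returns a two-column frame (q2, intracellular_fraction), strictly
    increasing in q2 and saturating below 1.
    """
    q2_arr = np.asarray(q2_values, dtype=float)
    if q2_arr.size == 0:
        raise ParameterError("q2_values must be non-empty")
    if np.any(q2_arr < 0) or not np.all(np.isfinite(q2_arr)):
        raise ParameterError("q2 values must be finite and >= 0")
    frac = np.array([intracellular_fraction(params, q2=float(q)) for q in q2_arr])
    return pd.DataFrame({"q2": q2_arr, "intracellular_fraction": frac})


def transit_time(params: RateConstants) -> float:
    """Overall PM -> RE -> LM -> PM transit time 1/k1 + 1/k2 + 1/k3 (min)."""
    _require_positive(params, ("k1", "k2", "k3"))
    return 1.0 / params.k1 + 1.0 / params.k2 + 1.0 / params.k3


def steady_state_summary(
    params: RateConstants, variant: str = "open_four"
) -> pd.DataFrame:
    """One-row summary frame (rates, q2, fractions, transit time) for export."""
    get_variant(variant)
    fractions = steady_state_fractions(params)
    row = {"variant": variant}
    row.update(params.as_dict())
    row["q2"] = q2_ratio(params.k4, params.km4)
    for key, value in zip(("frac_PM", "frac_RE", "frac_LM", "frac_ILV"), fractions):
        row[key] = round(float(value), 4)
    row["intracellular_fraction"] = round(float(fractions[1:].sum()), 4)
    row["transit_time_min"] = round(transit_time(params), 2)
    return pd.DataFrame([row])
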