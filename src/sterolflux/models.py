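"""Model definitions for sterol transport between plasma membrane and endo-lysosomes.

The cell is described by four well-mixed sterol pools:

=====  =======================================  ======
index  compartment                              symbol
=====  =======================================  ======
1      plasma membrane                          PM
2      recycling endosomes                      RE
3      limiting membrane of late endo/lysosome  LM
4      intraluminal vesicles                    ILV
=====  =======================================  ======

Transport between pools is first order, PM -> RE -> LM -> PM unidirectional
(cycling emerges from the loop), with bidirectional LM <-> ILV exchange whose
rates map the sterol-transfer activity of NPC2.  Model variants:

``closed_three``
    PM/RE/LM cycle only (k4 = k-4 = 0); describes healthy control cells.
``closed_four``
    adds the ILV pool; the slow LM <-> ILV exchange produces the biphasic
    endo-lysosomal accumulation seen in NPC2-deficient cells.
``open_four``
    adds constant sterol influx v0 into the PM and first-order efflux k5
    from the PM (continuous-uptake experiments); admits a steady state.
``efflux_two_pathway``
    no influx; efflux from the PM (pathway I, rate k5: ectosome shedding /
    transfer to ApoA1) and from the ILVs (pathway II: lysosomal exocytosis
    of ILVs as exosomes) with the time-dependent Weibull rate coefficient
    k(t) = mu * k6**mu * t**(mu-1), k6 = 1/tau.
``reversible_two_branch``
    two independent reversible branches PM <-> RE and PM <-> LE/LYS; a
    comparison model only (it cannot produce biphasic uptake).

All rates are per minute; amounts are in arbitrary fluorescence units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Iterable, Mapping

import numpy as np

from .errors import ParameterError

__all__ = [
    "RateConstants",
    "CompartmentState",
    "ModelVariant",
    "VARIANTS",
    "get_variant",
    "derivatives",
    "rate_matrix",
    "weibull_survival",
    "weibull_hazard",
    "weibull_consistency_check",
    "DISEASE_PARAMS",
    "CONTROL_PARAMS",
    "CONTROL_FULL_PARAMS",
]

_RATE_FIELDS = ("k1", "k2", "k3", "k4", "km4", "v0", "k5", "k6")


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of every model variant.

    Parameters
    ----------
    k1 : float
        PM -> RE transport rate (min^-1).
    k2 : float
        RE -> LM transport rate (min^-1).
    k3 : float
        LM -> PM transport rate (min^-1).
    k4 : float
        LM -> ILV transfer rate (min^-1).
    km4 : float
        ILV -> LM transfer rate (min^-1); written k_-4 in the field.
    v0 : float
        Constant sterol influx into the PM (amount * min^-1); the product of
        an uptake rate constant and the (excess) extracellular sterol pool.
    k5 : float
        First-order efflux rate from the PM (min^-1).
    k6 : float
        Inverse Weibull time constant for lysosomal exocytosis, 1/tau (min^-1).
    mu : float
        Weibull shape parameter (dimensionless); mu > 1 is a compressed
        exponential (delayed, accelerating export), mu = 1 plain exponential.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    km4: float = 0.0
    v0: float = 0.0
    k5: float = 0.0
    k6: float = 0.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ParameterError(
                    f"rate constant {name!r} must be finite and >= 0, got {value!r}"
                )
        if not math.isfinite(self.mu) or self.mu <= 0:
            raise ParameterError(f"shape parameter 'mu' must be > 0, got {self.mu!r}")

    def replace(self, **changes: float) -> "RateConstants":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Table-style parameter sets inferred from pulse-chase experiments in human
#: fibroblasts: NPC2-deficient ("disease") cells need the full four-pool
#: model; control cells are described by the three-pool cycle.
DISEASE_PARAMS = RateConstants(k1=0.03216, k2=0.4331, k3=0.1744, k4=0.0084, km4=0.0039)
CONTROL_PARAMS = RateConstants(k1=0.01204, k2=0.2465, k3=0.09351)
#: Control cells with restored LM<->ILV exchange (q2 = k4/k-4 = 0.2), the
#: rate pair inferred by matching the steady-state sterol fraction.
CONTROL_FULL_PARAMS = CONTROL_PARAMS.replace(k4=0.01686, km4=0.0843)


@dataclass(frozen=True)
class CompartmentState:
    """Sterol amounts n1..n4 in PM, RE, LM and ILV (fluorescence units)."""

    n1: float = 0.0
    n2: float = 0.0
    n3: float = 0.0
    n4: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ParameterError(
                    f"compartment amount {name!r} must be finite and >= 0, got {value!r}"
                )

    @property
    def array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "CompartmentState":
        n1, n2, n3, n4 = (float(v) for v in values)
        return cls(n1, n2, n3, n4)

    @property
    def total(self) -> float:
        return self.n1 + self.n2 + self.n3 + self.n4


# ---------------------------------------------------------------------------
# Weibull survival calculus (pathway II: lysosomal exocytosis)
# ---------------------------------------------------------------------------

def weibull_survival(t, tau: float, mu: float):
    """Weibull survival fraction S(t) = exp(-(t/tau)**mu).

    S(t) is the probability that a sterol molecule still resides in the
    endo-lysosomal pool at time ``t``; ``tau`` is the characteristic
    residence time and ``mu`` the shape parameter.
    """
    if not (math.isfinite(tau) and tau > 0):
        raise ParameterError(f"'tau' must be > 0, got {tau!r}")
    if not (math.isfinite(mu) and mu > 0):
        raise ParameterError(f"'mu' must be > 0, got {mu!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("'t' must be >= 0")
    out = np.exp(-((t_arr / tau) ** mu))
    return out if out.ndim else float(out)


def weibull_hazard(t, k6: float, mu: float):
    """Instantaneous export rate k(t) = mu * k6**mu * t**(mu-1) (min^-1).

    This is the hazard -d ln S/dt of :func:`weibull_survival` with
    k6 = 1/tau.  For mu > 1 the hazard vanishes at t = 0 (delayed export,
    defined by continuity); for mu = 1 it is the constant k6; for mu < 1 it
    diverges at the origin, so t = 0 is rejected there.
    """
    if not (math.isfinite(k6) and k6 >= 0):
        raise ParameterError(f"'k6' must be >= 0, got {k6!r}")
    if not (math.isfinite(mu) and mu > 0):
        raise ParameterError(f"'mu' must be > 0, got {mu!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("'t' must be >= 0")
    if mu == 1.0:
        out = np.full_like(t_arr, k6)
        return out if out.ndim else float(out)
    if mu < 1.0 and np.any(t_arr == 0):
        raise ParameterError("hazard diverges at t=0 for mu < 1")
    with np.errstate(divide="ignore"):
        out = mu * k6**mu * np.where(t_arr > 0, t_arr, 1.0) ** (mu - 1.0)
    out = np.where(t_arr > 0, out, 0.0)  # continuity limit for mu > 1
    return out if out.ndim else float(out)


def weibull_consistency_check(
    tau: float,
    mu: float,
    grid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> float:
    """Max |S_numeric - S_analytic| over ``grid``.

    Integrates dS/dt = -k(t) * S from S(0) = 1 with the hazard of
    :func:`weibull_hazard` and compares against the closed-form survival
    function — a self-consistency check of the hazard/survival pair.
    Returns the maximum absolute deviation (contract: < 1e-6 at defaults).
    """
    from scipy.integrate import solve_ivp

    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0 or np.any(grid_arr < 0):
        raise ParameterError("grid must be non-empty with t >= 0")
    if mu < 1.0 and np.any(grid_arr == 0):
        raise ParameterError("grid must lie in (0, T] for mu < 1")
    k6 = 1.0 / tau if tau > 0 else None
    if k6 is None:
        raise ParameterError(f"'tau' must be > 0, got {tau!r}")
    t0 = 0.0 if mu >= 1.0 else float(grid_arr.min()) * 1e-6
    t_end = float(grid_arr.max())
    sol = solve_ivp(
        lambda t, s: -weibull_hazard(t, k6, mu) * s,
        (t0, t_end),
        [1.0 if mu >= 1.0 else float(weibull_survival(t0, tau, mu))],
        t_eval=np.unique(np.concatenate([[t0], grid_arr])),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    analytic = weibull_survival(sol.t, tau, mu)
    return float(np.max(np.abs(sol.y[0] - analytic)))


# ---------------------------------------------------------------------------
# Model variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelVariant:
    """A named right-hand-side structure and its active parameter set."""

    name: str
    active_parameters: frozenset[str]
    description: str
    closed: bool
    matrix: Callable[[RateConstants, float], tuple[np.ndarray, np.ndarray]] = field(
        repr=False, compare=False, default=None
    )
    time_dependent: bool = False

    def validate_params(self, params: RateConstants) -> None:
        """Reject parameter sets that activate fields outside this variant."""
        inactive = set(_RATE_FIELDS) - self.active_parameters
        for name in sorted(inactive):
            if getattr(params, name) != 0.0:
                raise ParameterError(
                    f"parameter {name!r} must be 0 for variant {self.name!r} "
                    f"(got {getattr(params, name)!r})"
                )


def _matrix_closed_four(p: RateConstants, t: float = 0.0):
    a = np.array(
        [
            [-p.k1, 0.0, p.k3, 0.0],
            [p.k1, -p.k2, 0.0, 0.0],
            [0.0, p.k2, -(p.k3 + p.k4), p.km4],
            [0.0, 0.0, p.k4, -p.km4],
        ]
    )
    return a, np.zeros(4)


def _matrix_open_four(p: RateConstants, t: float = 0.0):
    a, _ = _matrix_closed_four(p)
    a[0, 0] = -(p.k1 + p.k5)
    return a, np.array([p.v0, 0.0, 0.0, 0.0])


def _matrix_efflux(p: RateConstants, t: float = 0.0):
    a, _ = _matrix_closed_four(p)
    a[0, 0] = -(p.k1 + p.k5)
    a[3, 3] = -p.km4 - weibull_hazard(t, p.k6, p.mu)
    return a, np.zeros(4)


def _matrix_two_branch(p: RateConstants, t: float = 0.0):
    # Reversible two-branch scheme: PM <-> RE with (k1, k2) and
    # PM <-> LE/LYS with (k3, k4); the ILV pool is unused.
    a = np.array(
        [
            [-(p.k1 + p.k3), p.k2, p.k4, 0.0],
            [p.k1, -p.k2, 0.0, 0.0],
            [p.k3, 0.0, -p.k4, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return a, np.zeros(4)


VARIANTS: Mapping[str, ModelVariant] = {
    "closed_three": ModelVariant(
        name="closed_three",
        active_parameters=frozenset({"k1", "k2", "k3"}),
        description="PM -> RE -> LM -> PM cycle, no ILV exchange (control cells)",
        closed=True,
        matrix=_matrix_closed_four,
    ),
    "closed_four": ModelVariant(
        name="closed_four",
        active_parameters=frozenset({"k1", "k2", "k3", "k4", "km4"}),
        description="closed cycle with bidirectional LM <-> ILV exchange",
        closed=True,
        matrix=_matrix_closed_four,
    ),
    "open_four": ModelVariant(
        name="open_four",
        active_parameters=frozenset({"k1", "k2", "k3", "k4", "km4", "v0", "k5"}),
        description="four-pool model with constant PM influx v0 and PM efflux k5",
        closed=False,
        matrix=_matrix_open_four,
    ),
    "efflux_two_pathway": ModelVariant(
        name="efflux_two_pathway",
        active_parameters=frozenset({"k1", "k2", "k3", "k4", "km4", "k5", "k6", "mu"}),
        description=(
            "two-pathway efflux: PM efflux k5 (ectosomes/ApoA1) and "
            "Weibull-delayed ILV export k(t) (exosome release)"
        ),
        closed=False,
        matrix=_matrix_efflux,
        time_dependent=True,
    ),
    "reversible_two_branch": ModelVariant(
        name="reversible_two_branch",
        active_parameters=frozenset({"k1", "k2", "k3", "k4"}),
        description=(
            "two independent reversible branches PM<->RE (k1, k2) and "
            "PM<->LE/LYS (k3, k4); comparison model only"
        ),
        closed=True,
        matrix=_matrix_two_branch,
    ),
}


def get_variant(variant: "str | ModelVariant") -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ParameterError(
            f"unknown model variant {variant!r}; choose from {sorted(VARIANTS)}"
        ) from None


def rate_matrix(
    variant: "str | ModelVariant", params: RateConstants, t: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, b) with dn/dt = A @ n + b for the variant at time ``t``.

    For constant-coefficient variants A is time-independent; the
    ``efflux_two_pathway`` variant embeds the Weibull hazard in A[3, 3].
    """
    var = get_variant(variant)
    var.validate_params(params)
    return var.matrix(params, t)


def derivatives(
    variant: "str | ModelVariant",
    params: RateConstants,
    state: "CompartmentState | Iterable[float]",
    t: float = 0.0,
) -> np.ndarray:
    """Instantaneous rates of change (dn1..dn4)/dt at state and time ``t``."""
    if not isinstance(state, CompartmentState):
        state = CompartmentState.from_array(state)
    if t < 0:
        raise ParameterError(f"'t' must be >= 0, got {t!r}")
    a, b = rate_matrix(variant, params, t)
    return a @ state.array + b
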