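"""Reaction mechanism and forward simulation of luciferase progress curves.

The catalytic cycle modelled here is the single-substrate Michaelis–Menten
mechanism extended by two dead-end equilibria:

    E + S <-> ES -> E + P        (binding k1/k_off, turnover k_cat)
    E + P <-> EP                 (product rebinding, dissociation constant K_p)
    ES + S <-> ESS               (substrate inhibition, dissociation constant K_s)

Under the quasi-steady-state approximation (QSSA) the product-formation rate is

    v = k_cat * E0 * S / ( K_m*(1 + P/K_p) + S*(1 + S/K_s) )

with K_m = (k_off + k_cat)/k1.  Finite K_p yields competitive product
inhibition (flash-type luminescence decay); finite K_s yields uncompetitive
substrate inhibition with a rate optimum at S* = sqrt(K_m*K_s).  K_p and K_s
may be ``inf`` to switch either pathway off.

Units are fixed package-wide: concentrations in µM, time in s, first-order
rates in s⁻¹ and second-order rates in µM⁻¹s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, DomainError, InfeasibleRateError

__all__ = [
    "KineticParams",
    "KineticScheme",
    "SchemeId",
    "AssayConditions",
    "ProgressCurve",
    "MicroRates",
    "rate_qssa",
    "integrate_progress",
    "derive_micro_rates",
    "simulate_mass_action",
]

#: default integrator tolerances (relative, absolute in µM)
DEFAULT_REL_TOL = 1e-8
DEFAULT_ABS_TOL = 1e-10


@dataclass(frozen=True)
class KineticParams:
    """Macroscopic kinetic constants for one enzyme–luciferin pair.

    Parameters
    ----------
    k_cat : float
        Turnover number, s⁻¹.
    K_m : float
        Michaelis constant, µM.
    K_p : float
        Dissociation constant of the enzyme–product complex, µM.
        ``inf`` disables product inhibition.
    K_s : float
        Dissociation constant of the dead-end enzyme–substrate–substrate
        complex, µM. ``inf`` disables substrate inhibition.
    """

    k_cat: float
    K_m: float
    K_p: float = math.inf
    K_s: float = math.inf

    def __post_init__(self):
        for name in ("k_cat", "K_m"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be finite and strictly positive, got {v}")
        for name in ("K_p", "K_s"):
            v = getattr(self, name)
            if not v > 0:
                raise DomainError(f"{name} must be strictly positive (or inf), got {v}")

    @property
    def specificity(self) -> float:
        """k_cat/K_m in s⁻¹µM⁻¹."""
        return self.k_cat / self.K_m


class SchemeId(str, Enum):
    MM_BASIC = "mm_basic"
    MM_PROD_INHIB = "mm_prod_inhib"
    MM_PROD_SUBS_INHIB = "mm_prod_subs_inhib"
    MASS_ACTION = "mass_action"


@dataclass(frozen=True)
class KineticScheme:
    """Selects which inhibition pathways are active in the forward model."""

    scheme_id: SchemeId = SchemeId.MM_PROD_INHIB
    dead_end_ESS: bool = False
    competitive_EP: bool = True

    def __post_init__(self):
        object.__setattr__(self, "scheme_id", SchemeId(self.scheme_id))

    def validate_against(self, params: KineticParams) -> None:
        if self.scheme_id == SchemeId.MM_PROD_SUBS_INHIB and not np.isfinite(params.K_s):
            raise DomainError("mm_prod_subs_inhib requires finite K_s")
        if self.scheme_id == SchemeId.MM_PROD_INHIB and not np.isfinite(params.K_p):
            raise DomainError("mm_prod_inhib requires finite K_p")

    def effective_params(self, params: KineticParams) -> KineticParams:
        """Project ``params`` onto this scheme (inactive pathways -> inf)."""
        self.validate_against(params)
        K_p, K_s = params.K_p, params.K_s
        if self.scheme_id == SchemeId.MM_BASIC:
            K_p, K_s = math.inf, math.inf
        elif self.scheme_id == SchemeId.MM_PROD_INHIB:
            K_s = K_s if self.dead_end_ESS else math.inf
        return KineticParams(params.k_cat, params.K_m, K_p, K_s)


@dataclass(frozen=True)
class AssayConditions:
    """Plate-reader injection assay layout.

    E0 and S0 are the post-injection total enzyme and substrate
    concentrations in µM.  Recording starts ``baseline_s`` seconds before
    injection and samples every ``read_interval_s`` up to ``max_duration_s``
    (measured from injection).
    """

    E0: float
    S0: float
    baseline_s: float = 10.0
    read_interval_s: float = 0.5
    max_duration_s: float = 1000.0
    temperature_label: str = "37 °C"

    def __post_init__(self):
        if self.E0 < 0:
            raise DomainError(f"E0 must be >= 0, got {self.E0}")
        if not self.S0 > 0:
            raise DomainError(f"S0 must be > 0, got {self.S0}")
        if not self.read_interval_s > 0:
            raise DomainError("read_interval_s must be > 0")
        if self.max_duration_s < self.baseline_s:
            raise DomainError("max_duration_s must be >= baseline_s")

    def read_times(self) -> np.ndarray:
        """Post-injection sampling grid (t = 0 at injection), in s."""
        n = int(np.floor(self.max_duration_s / self.read_interval_s + 1e-9))
        return self.read_interval_s * np.arange(1, n + 1)


@dataclass
class ProgressCurve:
    """Product time course [P](t); optionally all species trajectories."""

    times: np.ndarray
    product: np.ndarray
    S0: float
    E0: float
    species: Mapping[str, np.ndarray] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.product.shape:
            raise DomainError("times and product must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")


def rate_qssa(params: KineticParams, S: float, P: float, E0: float) -> float:
    """Quasi-steady-state product-formation rate, µM·s⁻¹.

    v = k_cat·E0·S / (K_m·(1 + P/K_p) + S·(1 + S/K_s))
    """
    if S < 0 or P < 0 or E0 < 0:
        raise DomainError(f"concentrations must be nonnegative (S={S}, P={P}, E0={E0})")
    if S == 0.0 or E0 == 0.0:
        return 0.0
    denom = params.K_m * (1.0 + P / params.K_p) + S * (1.0 + S / params.K_s)
    return params.k_cat * E0 * S / denom


def _qssa_rhs(params: KineticParams, S0: float, E0: float):
    k_cat, K_m, K_p, K_s = params.k_cat, params.K_m, params.K_p, params.K_s

    def rhs(t, y):
        P = min(max(y[0], 0.0), S0)
        S = S0 - P
        denom = K_m * (1.0 + P / K_p) + S * (1.0 + S / K_s)
        return [k_cat * E0 * S / denom]

    return rhs


def integrate_progress(
    params: KineticParams,
    cond: AssayConditions,
    scheme: KineticScheme = KineticScheme(),
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
    times: np.ndarray | None = None,
    dense: bool = False,
):
    """Integrate the QSSA rate law dP/dt = v(S0-P, P) over the read grid.

    Returns a :class:`ProgressCurve` on ``times`` (default: the conditions'
    read grid).  With ``dense=True`` returns ``(curve, sol)`` where ``sol``
    is the scipy dense-output object, usable to evaluate P at arbitrary
    times without re-integration.
    """
    if not (rel_tol > 0 and abs_tol > 0):
        raise DomainError("tolerances must be positive")
    eff = scheme.effective_params(params)
    t_eval = cond.read_times() if times is None else np.asarray(times, dtype=float)
    if t_eval.size == 0:
        raise DomainError("empty evaluation grid")
    if cond.E0 == 0.0:
        curve = ProgressCurve(t_eval, np.zeros_like(t_eval), cond.S0, cond.E0)
        return (curve, None) if dense else curve
    sol = solve_ivp(
        _qssa_rhs(eff, cond.S0, cond.E0),
        (0.0, float(t_eval[-1])),
        [0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
        dense_output=dense,
    )
    if not sol.success:
        raise ConvergenceError(
            f"progress-curve integration failed near t={sol.t[-1] if sol.t.size else 0:.3g} s: "
            f"{sol.message}",
            diagnostics=sol,
        )
    P = np.clip(sol.y[0], 0.0, cond.S0)
    curve = ProgressCurve(t_eval, P, cond.S0, cond.E0)
    return (curve, sol) if dense else curve


@dataclass(frozen=True)
class MicroRates:
    """Mass-action rate constants consistent with a macroscopic parameter set.

    k1, k_on_p, k_on_ss are second-order (µM⁻¹s⁻¹); the rest first-order (s⁻¹).
    """

    k1: float
    k_off: float
    k_cat: float
    k_on_p: float = 0.0
    k_off_p: float = 0.0
    k_on_ss: float = 0.0
    k_off_ss: float = 0.0

    def __post_init__(self):
        for name in ("k1", "k_off", "k_cat", "k_on_p", "k_off_p", "k_on_ss", "k_off_ss"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative")

    @property
    def K_m(self) -> float:
        return (self.k_off + self.k_cat) / self.k1

    @property
    def K_p(self) -> float:
        return self.k_off_p / self.k_on_p if self.k_on_p > 0 else math.inf

    @property
    def K_s(self) -> float:
        return self.k_off_ss / self.k_on_ss if self.k_on_ss > 0 else math.inf


def derive_micro_rates(params: KineticParams, k1: float = 100.0) -> MicroRates:
    """Bridge macroscopic constants to a mass-action rate set.

    One association rate ``k1`` is shared by all binding steps; K_m fixes
    k_off = k1·K_m − k_cat, and the EP / ESS equilibria get off-rates
    k1·K_p and k1·K_s so their dissociation constants are exact.
    """
    minimal = params.k_cat / params.K_m
    if k1 <= minimal:
        raise InfeasibleRateError(
            f"k1={k1} µM⁻¹s⁻¹ implies k_off <= 0; need k1 > k_cat/K_m = {minimal:.6g}",
            minimal_k1=minimal,
        )
    k_off = k1 * params.K_m - params.k_cat
    k_on_p = k1 if np.isfinite(params.K_p) else 0.0
    k_on_ss = k1 if np.isfinite(params.K_s) else 0.0
    return MicroRates(
        k1=k1,
        k_off=k_off,
        k_cat=params.k_cat,
        k_on_p=k_on_p,
        k_off_p=k_on_p * params.K_p if k_on_p else 0.0,
        k_on_ss=k_on_ss,
        k_off_ss=k_on_ss * params.K_s if k_on_ss else 0.0,
    )


def simulate_mass_action(
    rates: MicroRates,
    cond: AssayConditions,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
    times: np.ndarray | None = None,
) -> ProgressCurve:
    """Integrate the full mass-action network (species E, S, ES, ESS, EP, P).

    The returned ``product`` is the total product formed, free P plus
    enzyme-bound EP: each turnover emits one photon, so this is the
    luminescence-relevant quantity and the mass-action counterpart of the
    QSSA product curve (free P alone is in ``species``).  Conservation
    (enzyme: E+ES+ESS+EP = E0; substrate: S+ES+2·ESS+EP+P = S0) is checked
    at every output point to 1e-6 relative.
    """
    t_eval = cond.read_times() if times is None else np.asarray(times, dtype=float)
    k1, koff, kcat = rates.k1, rates.k_off, rates.k_cat
    konp, koffp = rates.k_on_p, rates.k_off_p
    kons, koffs = rates.k_on_ss, rates.k_off_ss

    def rhs(t, y):
        E, S, ES, ESS, EP, P = y
        bind = k1 * E * S
        unbind = koff * ES
        turn = kcat * ES
        pbind = konp * E * P
        punbind = koffp * EP
        ssbind = kons * ES * S
        ssunbind = koffs * ESS
        return [
            -bind + unbind + turn - pbind + punbind,
            -bind + unbind - ssbind + ssunbind,
            bind - unbind - turn - ssbind + ssunbind,
            ssbind - ssunbind,
            pbind - punbind,
            turn - pbind + punbind,
        ]

    y0 = [cond.E0, cond.S0, 0.0, 0.0, 0.0, 0.0]
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        raise ConvergenceError(
            f"mass-action integration failed near t={sol.t[-1] if sol.t.size else 0:.3g} s: "
            f"{sol.message}",
            diagnostics=sol,
        )
    E, S, ES, ESS, EP, P = sol.y
    enz = E + ES + ESS + EP
    sub = S + ES + 2.0 * ESS + EP + P
    tol_e = 1e-6 * max(cond.E0, abs_tol)
    tol_s = 1e-6 * cond.S0
    if cond.E0 > 0 and np.max(np.abs(enz - cond.E0)) > tol_e:
        raise ConvergenceError(
            f"enzyme conservation violated by {np.max(np.abs(enz - cond.E0)):.3g} µM; "
            "tighten integrator tolerances"
        )
    if np.max(np.abs(sub - cond.S0)) > tol_s:
        raise ConvergenceError(
            f"substrate conservation violated by {np.max(np.abs(sub - cond.S0)):.3g} µM; "
            "tighten integrator tolerances"
        )
    species = {"E": E, "S": S, "ES": ES, "ESS": ESS, "EP": EP, "P": P}
    total_product = np.clip(P + EP, 0.0, cond.S0)
    return ProgressCurve(t_eval, total_product, cond.S0, cond.E0, species=species)
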