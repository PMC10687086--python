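"""Stage 3: derived quantities with propagated errors and identifiability maps.

Specificity constants (k_cat/K_m) and fold changes between variants are
ratios of fitted estimates; their standard errors use first-order (delta
method) propagation under independence,

    se(x/y) = (x/y)·sqrt((se_x/x)² + (se_y/y)²),

which the published tables implicitly assume (they print ± values without
covariances).  Where correlation matters, the confidence-contour machinery
is the corrective: for a pair of parameters it maps the chi² objective with
*all remaining parameters re-optimized at every grid node* and draws the
region under an F-statistic threshold

    chi²_thresh = chi²_min · (1 + p/(n−p) · F_{p, n−p}(conf)),

the standard boundary rule for nonlinear least squares confidence regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist

from .errors import ConvergenceError, DomainError
from .reference import ReferenceRow, ratio_consistent_with_printed

__all__ = [
    "DerivedQuantity",
    "ContourMap",
    "specificity_constant",
    "fold_change",
    "confidence_contours",
    "profile_chi2",
    "chi2_threshold",
    "table_consistency",
]


@dataclass(frozen=True)
class DerivedQuantity:
    name: str
    value: float
    se: float
    components: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise DomainError(f"{self.name} is not finite")
        if self.se < 0:
            raise DomainError("standard error must be nonnegative")


def specificity_constant(
    k_cat: float, se_k_cat: float, K_m: float, se_K_m: float
) -> DerivedQuantity:
    """k_cat/K_m in s⁻¹µM⁻¹ with first-order propagated standard error."""
    if not K_m > 0:
        raise DomainError("K_m must be strictly positive")
    value = k_cat / K_m
    se = abs(value) * math.hypot(se_k_cat / k_cat, se_K_m / K_m) if k_cat != 0 else 0.0
    return DerivedQuantity("specificity_constant", value, se, ((k_cat, se_k_cat), (K_m, se_K_m)))


def fold_change(
    variant_value: float, variant_se: float, reference_value: float, reference_se: float
) -> DerivedQuantity:
    """variant/reference ratio with independent first-order error propagation."""
    if not reference_value > 0:
        raise DomainError("reference value must be strictly positive")
    value = variant_value / reference_value
    se = (
        abs(value) * math.hypot(variant_se / variant_value, reference_se / reference_value)
        if variant_value != 0
        else 0.0
    )
    return DerivedQuantity(
        "fold_change", value, se, ((variant_value, variant_se), (reference_value, reference_se))
    )


def table_consistency(rows: Sequence[ReferenceRow]) -> list[dict]:
    """Recompute k_cat/K_m for published rows and flag printing inconsistencies.

    A row is consistent when the computed ratio rounds to the printed value
    at the printed decimal precision (half-ulp rule).
    """
    report = []
    for r in rows:
        q = specificity_constant(r.k_cat, r.se_k_cat, r.K_m, r.se_K_m)
        report.append(
            {
                "variant": r.variant,
                "luciferin": r.luciferin,
                "computed": q.value,
                "computed_se": q.se,
                "printed": r.printed_specificity,
                "consistent": ratio_consistent_with_printed(q.value, r.printed_specificity),
            }
        )
    return report


# ---------------------------------------------------------------------------
# Confidence contours (profile chi² over a parameter pair)
# ---------------------------------------------------------------------------


@runtime_checkable
class ProfileProblem(Protocol):
    """Anything the contour machinery can profile.

    :class:`lucikin.global_fit.FitProblem` satisfies this; tests also use
    small analytic problems (e.g. linear-Gaussian models).
    """

    param_names: Sequence[str]

    def residuals_from_dict(self, values: dict) -> np.ndarray: ...

    def log_scale(self, name: str) -> bool: ...


@dataclass
class ContourMap:
    """Profile-chi² surface over a parameter pair with a threshold boundary."""

    param_pair: tuple[str, str]
    axis_x: np.ndarray  # natural units
    axis_y: np.ndarray
    chi2_surface: np.ndarray  # shape (len(axis_y), len(axis_x)); NaN = node failed
    threshold: float
    chi2_min: float
    best_fit: tuple[float, float]

    @property
    def inside_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.chi2_surface <= self.threshold

    def to_frame(self):
        import pandas as pd

        X, Y = np.meshgrid(self.axis_x, self.axis_y)
        return pd.DataFrame(
            {
                self.param_pair[0]: X.ravel(),
                self.param_pair[1]: Y.ravel(),
                "chi2": self.chi2_surface.ravel(),
                "inside": self.inside_mask.ravel(),
            }
        )


def chi2_threshold(
    chi2_min: float, n_points: int, n_params: int, n_profiled: int = 2,
    confidence: float = 0.95, rule: str = "ftest",
) -> float:
    """Objective level delimiting the confidence region of a profiled subset.

    ``rule='ftest'`` is the classical nonlinear-least-squares boundary for a
    region over ``n_profiled`` parameters with the rest re-optimized:
    chi²_min·(1 + q/(n−p)·F_{q,n−p}(conf)), q = n_profiled, p = n_params.
    ``rule='ftest_all'`` sets q = p (the joint all-parameter region, the rule
    FitSpace-style maps use; conservative for a pair).  ``rule='chi2'`` uses
    the chi²_q quantile scaled by the variance estimate.
    """
    p, n = n_params, n_points
    if n <= p:
        raise DomainError("need more points than parameters")
    s2 = chi2_min / (n - p)
    if rule == "ftest":
        q = n_profiled
        return chi2_min + q * s2 * f_dist.ppf(confidence, q, n - p)
    if rule == "ftest_all":
        return chi2_min + p * s2 * f_dist.ppf(confidence, p, n - p)
    if rule == "chi2":
        return chi2_min + s2 * chi2_dist.ppf(confidence, n_profiled)
    raise DomainError(f"unknown threshold rule {rule!r}")


def _reoptimize(
    problem: ProfileProblem,
    fixed: dict,
    init: dict,
    bounds_nat=None,
) -> tuple[float, dict]:
    """Minimize chi² over the non-fixed parameters; returns (chi2, solution)."""
    free = [n for n in problem.param_names if n not in fixed]
    if not free:
        r = problem.residuals_from_dict(dict(fixed))
        return float(r @ r), dict(fixed)

    def pack(values):
        return np.array(
            [math.log(values[n]) if problem.log_scale(n) else values[n] for n in free]
        )

    def unpack(x):
        vals = dict(fixed)
        for n, v in zip(free, x):
            vals[n] = math.exp(v) if problem.log_scale(n) else float(v)
        return vals

    lo, hi = [], []
    for n in free:
        if bounds_nat and n in bounds_nat:
            b = bounds_nat[n]
            if problem.log_scale(n):
                lo.append(math.log(b[0]) if b[0] > 0 else -np.inf)
                hi.append(math.log(b[1]) if np.isfinite(b[1]) else np.inf)
            else:
                lo.append(b[0])
                hi.append(b[1])
        else:
            lo.append(-np.inf)
            hi.append(np.inf)

    def fun(x):
        return problem.residuals_from_dict(unpack(x))

    res = least_squares(
        fun, pack(init), bounds=(np.array(lo), np.array(hi)), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-10, x_scale="jac", max_nfev=2000,
    )
    if not res.success:
        raise ConvergenceError(f"re-optimization failed with fixed {fixed}")
    return 2.0 * float(res.cost), unpack(res.x)


def profile_chi2(
    problem: ProfileProblem,
    best_values: dict,
    fixed: dict,
    bounds_nat: dict | None = None,
) -> float:
    """Chi² with ``fixed`` parameters pinned and everything else re-optimized."""
    chi2, _ = _reoptimize(problem, fixed, {k: v for k, v in best_values.items() if k not in fixed},
                          bounds_nat)
    return chi2


def confidence_contours(
    problem: ProfileProblem,
    best_values: dict,
    chi2_min: float,
    n_points: int,
    pair: tuple[str, str],
    grid_n: int = 41,
    span: float = 10.0,
    confidence: float = 0.95,
    threshold_rule: str = "ftest",
    bounds_nat: dict | None = None,
) -> ContourMap:
    """FitSpace-style confidence contour for one parameter pair.

    The grid spans ×/÷``span`` around the estimate (log-spaced) for
    log-scale parameters, or ±``span``·|estimate| linearly otherwise.  At
    every node the pair is held fixed and all remaining parameters —
    including nuisance scaling factors and concentration corrections — are
    re-optimized from the best fit.  Nodes where re-optimization fails are
    flagged as NaN rather than interpolated.
    """
    px, py = pair
    for name in pair:
        if name not in problem.param_names:
            raise DomainError(f"{name!r} is not a fitted parameter")

    def axis(name):
        v = best_values[name]
        if problem.log_scale(name):
            return np.geomspace(v / span, v * span, grid_n)
        w = abs(v) * span if v != 0 else span
        return np.linspace(v - w, v + w, grid_n)

    ax, ay = axis(px), axis(py)
    n_params = len(problem.param_names)
    threshold = chi2_threshold(chi2_min, n_points, n_params, 2, confidence, threshold_rule)

    surface = np.full((grid_n, grid_n), np.nan)
    # walk outward from the best-fit corner so warm starts stay close
    warm = {j: {k: v for k, v in best_values.items()} for j in range(grid_n)}
    for iy, vy in enumerate(ay):
        init = dict(best_values)
        for ix, vx in enumerate(ax):
            try:
                chi2, sol = _reoptimize(
                    problem, {px: vx, py: vy},
                    {k: v for k, v in init.items() if k not in (px, py)},
                    bounds_nat,
                )
                surface[iy, ix] = chi2
                init = sol
            except ConvergenceError:
                continue
    return ContourMap(
        param_pair=pair,
        axis_x=ax,
        axis_y=ay,
        chi2_surface=surface,
        threshold=threshold,
        chi2_min=chi2_min,
        best_fit=(best_values[px], best_values[py]),
    )


def contour_contains(
    problem: ProfileProblem,
    best_values: dict,
    chi2_min: float,
    n_points: int,
    point: dict,
    confidence: float = 0.95,
    threshold_rule: str = "ftest",
    bounds_nat: dict | None = None,
) -> bool:
    """Whether an arbitrary parameter point lies inside the confidence region."""
    chi2 = profile_chi2(problem, best_values, point, bounds_nat)
    thr = chi2_threshold(
        chi2_min, n_points, len(problem.param_names), len(point), confidence, threshold_rule
    )
    return bool(chi2 <= thr)


def mc_ratio_se(
    numerator: tuple[float, float],
    denominator: tuple[float, float],
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo standard error of a ratio of independent Gaussians.

    Cross-check for the first-order propagation; valid for small CVs where
    the denominator stays safely positive.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(numerator[0], numerator[1], n_draws)
    y = rng.normal(denominator[0], denominator[1], n_draws)
    return float(np.std(x / y, ddof=1))
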