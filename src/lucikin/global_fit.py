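"""Stage 2: global fitting of full conversion curves across a series.

All curves of an enzyme–luciferin study (five substrate levels spanning
0.25–4×K_m, with replicates) are fitted simultaneously to the forward model

    C_model(t; θ) = f · P(t; k_cat, K_m, K_p[, K_s], S0·c, E0)

where P is the integrated quasi-steady-state progress curve, f the
luminescence scaling factor (RLU·s per µM, shared within a study and well
defined by the end state of completed curves) and c a per-curve
concentration correction bounded to ±5%.  Residuals are normalized by the
per-point sigma; the objective is the plain chi².  Kinetic parameters and
scaling factors are fitted in log space, which enforces positivity and
copes with the three-decade spread of published constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, ConvergenceError, DomainError
from .kinetic_core import (
    AssayConditions,
    KineticParams,
    KineticScheme,
    SchemeId,
    integrate_progress,
)
from .signal_model import ConversionCurve, LuminescenceTrace, cumulative_luminescence, subtract_baseline

__all__ = [
    "CurveData",
    "FitOptions",
    "FitResult",
    "FitProblem",
    "datasets_from_traces",
    "chi_squared",
    "fit_global",
    "check_depletion",
]

#: hard box for the ±5% concentration corrections
CONC_CORRECTION_BOUNDS = (0.95, 1.05)
#: log-space half-width of the parameter box around the initial guess
LOG_BOX_HALF_WIDTH = math.log(1e6)


@dataclass
class CurveData:
    """One conversion curve prepared for fitting (baseline-trimmed, RLU·s)."""

    S0: float  # nominal, µM
    E0: float  # µM
    times: np.ndarray  # s from injection
    cumulative: np.ndarray  # RLU·s
    sigma: np.ndarray  # RLU·s, strictly positive
    variant: str = ""
    luciferin: str = ""
    replicate: int = 1
    group: str = "default"  # scaling-factor group
    is_calibration: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.sigma is None:
            raise ConfigError(
                "curve lacks per-point sigma; supply instrument sigma or replicate scatter "
                "(fitting without weights is refused)"
            )
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ConfigError("sigma must be strictly positive at every point")


def datasets_from_traces(
    traces: list[LuminescenceTrace], include_calibration: bool = False
) -> list[CurveData]:
    """Baseline-subtract, accumulate and package raw traces for fitting.

    Scaling groups default to one group per (variant, luciferin) pair.
    Calibration wells (excess enzyme) are excluded unless requested; they are
    meant for :func:`lucikin.signal_model.calibrate_scaling`, not for the
    kinetic fit.
    """
    out = []
    for trace in traces:
        if trace.meta.get("is_calibration") and not include_calibration:
            continue
        trimmed = subtract_baseline(trace, trace.meta.get("baseline_s", 10.0))
        curve = cumulative_luminescence(trimmed)
        meta = trace.meta
        out.append(
            CurveData(
                S0=float(meta["S0_uM"]),
                E0=float(meta["E0_uM"]),
                times=curve.times,
                cumulative=curve.cumulative,
                sigma=curve.sigma,
                variant=str(meta.get("variant", "")),
                luciferin=str(meta.get("luciferin", "")),
                replicate=int(meta.get("replicate", 1)),
                group=f"{meta.get('variant', '')}|{meta.get('luciferin', '')}",
                is_calibration=bool(meta.get("is_calibration", False)),
            )
        )
    return out


@dataclass(frozen=True)
class FitOptions:
    """Switches for the global fit."""

    fit_Ks: bool = False
    fit_conc_corrections: bool = False
    observable: str = "cumulative"  # or "intensity" (diagnostic mode)
    fixed_scaling: dict | None = None  # group -> f, e.g. from calibration
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    multistart_n: int = 8

    def __post_init__(self):
        if self.observable not in ("cumulative", "intensity"):
            raise ConfigError(f"unknown observable {self.observable!r}")


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics from a global fit."""

    params: KineticParams
    se: dict
    scaling_f: dict
    conc_corrections: list
    chi2: float
    n_points: int
    n_params: int
    converged: bool
    init_record: dict = field(default_factory=dict)
    boundary_warnings: list = field(default_factory=list)
    values: dict = field(default_factory=dict)  # full parameter dict incl. nuisance

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / max(self.n_points - self.n_params, 1)


class FitProblem:
    """Weighted least-squares problem over kinetic + nuisance parameters.

    Exposes the generic profile interface consumed by
    :mod:`lucikin.uncertainty`: ``param_names``, ``log_scale``,
    ``bounds_nat`` and ``residuals_from_dict``.
    """

    def __init__(
        self,
        datasets: list[CurveData],
        scheme: KineticScheme = KineticScheme(),
        options: FitOptions = FitOptions(),
    ):
        if not datasets:
            raise ConfigError("no datasets to fit")
        self.datasets = list(datasets)
        self.scheme = scheme
        self.options = options
        fixed = options.fixed_scaling or {}
        self.groups = sorted({d.group for d in self.datasets})
        self.fixed_scaling = {g: fixed[g] for g in self.groups if g in fixed}

        names = ["k_cat", "K_m"]
        if scheme.scheme_id in (SchemeId.MM_PROD_INHIB, SchemeId.MM_PROD_SUBS_INHIB):
            names.append("K_p")
        if options.fit_Ks or scheme.scheme_id == SchemeId.MM_PROD_SUBS_INHIB:
            names.append("K_s")
        for g in self.groups:
            if g not in self.fixed_scaling:
                names.append(f"f[{g}]")
        if options.fit_conc_corrections:
            names += [f"c[{i}]" for i in range(len(self.datasets))]
        self.param_names = names
        self.n_points = int(sum(d.times.size for d in self.datasets))

    # -- profile interface ------------------------------------------------
    def log_scale(self, name: str) -> bool:
        return not name.startswith("c[")

    def bounds_nat(self, name: str) -> tuple[float, float]:
        if name.startswith("c["):
            return CONC_CORRECTION_BOUNDS
        return (0.0, np.inf)

    # -- model ------------------------------------------------------------
    def _kinetic_params(self, values: dict) -> KineticParams:
        return KineticParams(
            k_cat=values["k_cat"],
            K_m=values["K_m"],
            K_p=values.get("K_p", math.inf),
            K_s=values.get("K_s", math.inf),
        )

    def model_for(self, values: dict, cache: dict | None = None) -> list[np.ndarray]:
        """Model observable for every dataset at the given parameter values."""
        params = self._kinetic_params(values)
        cache = {} if cache is None else cache
        out = []
        for i, d in enumerate(self.datasets):
            c = values.get(f"c[{i}]", 1.0)
            f = self.fixed_scaling.get(d.group, values.get(f"f[{d.group}]"))
            key = (round(d.S0 * c, 14), d.E0)
            sol = cache.get(key)
            t_max = float(d.times[-1])
            if sol is None or sol[0] < t_max:
                cond = AssayConditions(
                    E0=d.E0, S0=d.S0 * c, baseline_s=0.0,
                    read_interval_s=1.0, max_duration_s=t_max,
                )
                _, dense = integrate_progress(
                    params, cond, self.scheme,
                    rel_tol=self.options.rel_tol, abs_tol=self.options.abs_tol,
                    times=np.array([t_max]), dense=True,
                )
                sol = (t_max, dense, d.S0 * c, d.E0)
                cache[key] = sol
            _, dense, S0_eff, E0 = sol
            if dense is None:  # E0 == 0
                P = np.zeros_like(d.times)
            else:
                P = np.clip(dense.sol(d.times)[0], 0.0, S0_eff)
            if self.options.observable == "cumulative":
                out.append(f * P)
            else:
                dt = np.diff(d.times, prepend=0.0)
                out.append(f * np.diff(P, prepend=0.0) / dt)
        return out

    def _observed(self, d: CurveData) -> tuple[np.ndarray, np.ndarray]:
        if self.options.observable == "cumulative":
            return d.cumulative, d.sigma
        dt = np.diff(d.times, prepend=0.0)
        intens = np.diff(d.cumulative, prepend=0.0) / dt
        sig = np.diff(d.sigma**2, prepend=0.0)
        sig = np.sqrt(np.maximum(sig, np.finfo(float).tiny)) / dt
        return intens, sig

    def residuals_from_dict(self, values: dict) -> np.ndarray:
        cache: dict = {}
        models = self.model_for(values, cache)
        res = []
        for d, m in zip(self.datasets, models):
            obs, sig = self._observed(d)
            res.append((m - obs) / sig)
        return np.concatenate(res)

    # -- internal vector transform ----------------------------------------
    def to_internal(self, values: dict) -> np.ndarray:
        return np.array(
            [math.log(values[n]) if self.log_scale(n) else values[n] for n in self.param_names]
        )

    def to_natural(self, x: np.ndarray) -> dict:
        return {
            n: (math.exp(v) if self.log_scale(n) else float(v))
            for n, v in zip(self.param_names, x)
        }

    def internal_bounds(self, init: dict) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for n in self.param_names:
            if self.log_scale(n):
                center = math.log(init[n])
                lo.append(center - LOG_BOX_HALF_WIDTH)
                hi.append(center + LOG_BOX_HALF_WIDTH)
            else:
                b = self.bounds_nat(n)
                lo.append(b[0])
                hi.append(b[1])
        return np.array(lo), np.array(hi)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self.residuals_from_dict(self.to_natural(x))

    def default_init(self, params: KineticParams | None = None) -> dict:
        """Heuristic starting values (scaling from the largest plateau/S0)."""
        init: dict = {}
        if params is not None:
            init.update(k_cat=params.k_cat, K_m=params.K_m)
            if "K_p" in self.param_names:
                init["K_p"] = params.K_p if np.isfinite(params.K_p) else 1.0
            if "K_s" in self.param_names:
                init["K_s"] = params.K_s if np.isfinite(params.K_s) else 10.0
        else:
            S_mid = float(np.median([d.S0 for d in self.datasets]))
            v_guess = max(
                float(np.max(np.diff(d.cumulative) / np.diff(d.times))) for d in self.datasets
            )
            init.update(k_cat=1.0, K_m=S_mid, K_p=S_mid, K_s=10 * S_mid)
            init = {k: init[k] for k in ["k_cat", "K_m"] + [n for n in ("K_p", "K_s") if n in self.param_names]}
        for g in self.groups:
            if g in self.fixed_scaling:
                continue
            curves = [d for d in self.datasets if d.group == g]
            init[f"f[{g}]"] = max(float(d.cumulative[-1]) / d.S0 for d in curves)
        for n in self.param_names:
            if n.startswith("c["):
                init[n] = 1.0
        return init


def chi_squared(
    params: KineticParams,
    nuisance: dict,
    datasets: list[CurveData],
    scheme: KineticScheme = KineticScheme(),
    options: FitOptions = FitOptions(),
) -> float:
    """Sigma-normalized objective Σ((model − data)/σ)² at fixed parameters.

    ``nuisance`` carries ``scaling_f`` (group → f) and optionally
    ``conc_corrections`` (list aligned with datasets).
    """
    problem = FitProblem(datasets, scheme, options)
    values = {"k_cat": params.k_cat, "K_m": params.K_m}
    if "K_p" in problem.param_names:
        values["K_p"] = params.K_p
    if "K_s" in problem.param_names:
        values["K_s"] = params.K_s
    scaling = nuisance.get("scaling_f", {})
    if not isinstance(scaling, dict):
        scaling = {g: scaling for g in problem.groups}
    for g in problem.groups:
        if g in problem.fixed_scaling:
            continue
        if g not in scaling:
            raise ConfigError(f"missing scaling factor for group {g!r}")
        values[f"f[{g}]"] = scaling[g]
    corrections = nuisance.get("conc_corrections")
    if options.fit_conc_corrections:
        corrections = corrections or [1.0] * len(datasets)
        for i, c in enumerate(corrections):
            values[f"c[{i}]"] = c
    r = problem.residuals_from_dict(values)
    return float(np.dot(r, r))


def fit_global(
    datasets: list[CurveData],
    scheme: KineticScheme = KineticScheme(),
    init: KineticParams | dict | None = None,
    multistart_n: int | None = None,
    seed: int = 0,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Bounded multistart nonlinear least squares over all curves at once.

    ``init`` may be a :class:`KineticParams` (e.g. stage-1 estimates) or a
    full value dict; missing entries fall back to data-driven heuristics.
    The best of ``multistart_n`` seeded log-perturbed (×/÷3) starts wins;
    ties break on lower chi², then on smaller parameter-vector norm.
    """
    problem = FitProblem(datasets, scheme, options)
    n_starts = options.multistart_n if multistart_n is None else multistart_n
    if isinstance(init, dict):
        init_values = dict(init)
        base = problem.default_init()
        for k in problem.param_names:
            init_values.setdefault(k, base[k])
    else:
        init_values = problem.default_init(init)
    x0 = problem.to_internal(init_values)
    lo, hi = problem.internal_bounds(init_values)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        pert = np.array(
            [
                rng.uniform(-math.log(3.0), math.log(3.0)) if problem.log_scale(n) else 0.0
                for n in problem.param_names
            ]
        )
        starts.append(np.clip(x0 + pert, lo, hi))

    best = None
    diagnostics = []
    for k, s in enumerate(starts):
        try:
            res = least_squares(
                problem.residuals, s, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-12, x_scale="jac", max_nfev=4000,
            )
            diagnostics.append({"start": k, "chi2": 2 * res.cost, "status": res.status})
        except Exception as exc:  # keep going; report per-start failures
            diagnostics.append({"start": k, "error": str(exc)})
            continue
        if best is None:
            best = res
        else:
            c_new, c_old = 2 * res.cost, 2 * best.cost
            if c_new < c_old * (1 - 1e-12) or (
                abs(c_new - c_old) <= 1e-12 * max(c_old, 1.0)
                and np.linalg.norm(res.x) < np.linalg.norm(best.x)
            ):
                best = res
    if best is None:
        raise ConvergenceError("global fit failed in every start", diagnostics=diagnostics)

    values = problem.to_natural(best.x)
    chi2 = 2.0 * float(best.cost)
    n_params = len(problem.param_names)
    converged = bool(best.success)

    warnings = []
    for n, v, l, h in zip(problem.param_names, best.x, lo, hi):
        if h - l > 0 and (v - l < 1e-6 * (h - l) or h - v < 1e-6 * (h - l)):
            warnings.append(f"parameter {n} at a bound")

    se: dict = {}
    if converged:
        dof = max(problem.n_points - n_params, 1)
        s2 = chi2 / dof
        try:
            cov = np.linalg.inv(best.jac.T @ best.jac) * s2
            sig = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for n, s_log in zip(problem.param_names, sig):
                se[n] = values[n] * s_log if problem.log_scale(n) else s_log
        except np.linalg.LinAlgError:
            se = {n: float("nan") for n in problem.param_names}

    params = problem._kinetic_params(values)
    scaling = dict(problem.fixed_scaling)
    scaling.update({g: values[f"f[{g}]"] for g in problem.groups if f"f[{g}]" in values})
    corrections = [values.get(f"c[{i}]", 1.0) for i in range(len(datasets))]

    return FitResult(
        params=params,
        se=se,
        scaling_f=scaling,
        conc_corrections=corrections,
        chi2=chi2,
        n_points=problem.n_points,
        n_params=n_params,
        converged=converged,
        init_record={"seed": seed, "multistart_n": n_starts, "init": init_values,
                     "per_start": diagnostics},
        boundary_warnings=warnings,
        values=values,
    )


def check_depletion(calibrated_curve: ConversionCurve, S0: float) -> tuple[float, bool]:
    """Terminal conversion fraction P_end/S0 and the >=99.5% pass flag."""
    if not calibrated_curve.calibrated:
        raise DomainError("depletion check needs a calibrated (µM) curve")
    if not S0 > 0:
        raise DomainError("S0 must be positive")
    fraction = float(calibrated_curve.cumulative[-1] / S0)
    return fraction, fraction >= 0.995
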