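"""Stage 1: initial velocities from 15-s reads and the Michaelis–Menten fit.

Short post-injection reads (15 s, <5% conversion) give initial velocities
v0(S0); nonlinear regression of

    v0 = Vmax·S / (K_m + S + S²/K_s)

then yields a provisional K_m used to lay out the 0.25–4×K_m progress-curve
series and to seed the global fit.  The velocity is taken as the slope of
the cumulative curve over the window rather than the first intensity read —
integration averages the noise and matches initial-velocity semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, DomainError
from .signal_model import ConversionCurve

__all__ = ["VelocityPoint", "InitialRateFit", "initial_velocity", "fit_initial_rates"]

#: K_s above this multiple of max(S0) is reported as "no detectable substrate inhibition"
KS_BOUND_MULTIPLE = 1e4


@dataclass(frozen=True)
class VelocityPoint:
    """One (substrate, initial velocity) observation."""

    S0: float
    v0: float
    se_v0: float | None = None

    def __post_init__(self):
        if not self.S0 > 0:
            raise DomainError("S0 must be positive")
        if self.v0 < 0:
            raise DomainError("v0 must be nonnegative")


@dataclass
class InitialRateFit:
    Vmax: float
    K_m: float
    K_s: float | None  # None when substrate inhibition not fitted
    se_Vmax: float
    se_K_m: float
    se_K_s: float | None
    converged: bool
    chi2: float
    substrate_inhibition_detected: bool


def initial_velocity(curve: ConversionCurve, window_s: float = 15.0) -> VelocityPoint:
    """Least-squares slope of the cumulative signal over the initial window.

    Returns the velocity in the curve's own units (µM/s when calibrated,
    RLU/s otherwise) with the regression standard error.
    """
    if not window_s > 0:
        raise DomainError("window_s must be positive")
    if curve.times.max() < window_s - 1e-9:
        raise DomainError(
            f"curve extent {curve.times.max():.3g} s does not cover the {window_s} s window"
        )
    mask = curve.times <= window_s + 1e-9
    t, y = curve.times[mask], curve.cumulative[mask]
    if t.size < 3:
        raise DomainError("need at least 3 points in the velocity window")
    # slope through the injection origin is biased by baseline offsets; fit
    # an affine model and report the slope
    A = np.vstack([t, np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    dof = t.size - 2
    if dof > 0 and res.size:
        s2 = float(res[0]) / dof
        se = float(np.sqrt(s2 / np.sum((t - t.mean()) ** 2)))
    else:
        se = 0.0
    S0 = float(curve.meta.get("S0_uM", np.nan))
    if not np.isfinite(S0):
        raise DomainError("curve metadata must carry S0_uM")
    return VelocityPoint(S0=S0, v0=max(slope, 0.0), se_v0=se if se > 0 else None)


def _mm_model(S: np.ndarray, Vmax: float, K_m: float, K_s: float) -> np.ndarray:
    return Vmax * S / (K_m + S + S**2 / K_s)


def fit_initial_rates(
    points: list[VelocityPoint], substrate_inhibition: bool = False
) -> InitialRateFit:
    """Weighted nonlinear regression of v0(S0) to the rate law.

    Weights are 1/se² where standard errors are available, else unweighted.
    Parameters are fitted in log space (positivity); multistart from the
    half-Vmax crossing heuristic plus coarse perturbations.  When the fitted
    K_s runs into its upper bound the substrate-inhibition term is declared
    undetectable and the reduced (K_s = ∞) fit is reported.
    """
    if len(points) < (4 if substrate_inhibition else 3):
        raise DomainError("too few velocity points for the requested model")
    S = np.array([p.S0 for p in points])
    v = np.array([p.v0 for p in points])
    se = np.array([p.se_v0 if p.se_v0 else np.nan for p in points])
    weighted = bool(np.all(np.isfinite(se)))
    w = 1.0 / se if weighted else np.ones_like(v)

    vmax0 = float(v.max()) * 1.2
    half = vmax0 / 2.0
    above = S[v >= half]
    km0 = float(above.min()) if above.size else float(np.median(S))
    ks_bound = KS_BOUND_MULTIPLE * float(S.max())
    ks0 = 10.0 * float(S.max())

    n_par = 3 if substrate_inhibition else 2

    def residuals(theta):
        Vmax, K_m = np.exp(theta[0]), np.exp(theta[1])
        K_s = np.exp(theta[2]) if substrate_inhibition else np.inf
        return w * (_mm_model(S, Vmax, K_m, K_s) - v)

    starts = [np.log([vmax0, km0] + ([ks0] if substrate_inhibition else []))]
    for f in (3.0, 1 / 3.0):
        starts.append(starts[0] + np.log(f))
    best = None
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ConvergenceError("initial-rate fit failed from every start")

    Vmax, K_m = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    K_s = float(np.exp(best.x[2])) if substrate_inhibition else None
    chi2 = 2.0 * float(best.cost)
    dof = max(S.size - n_par, 1)

    # covariance of log-parameters from the Jacobian at the optimum; with
    # caller-supplied sigmas the noise scale is known, otherwise estimate it
    J = best.jac
    scale = 1.0 if weighted else chi2 / dof
    try:
        cov = np.linalg.inv(J.T @ J) * scale
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(n_par, np.nan)

    detected = substrate_inhibition and K_s is not None and K_s < ks_bound
    if substrate_inhibition and not detected:
        # K_s unidentifiable: report the reduced model instead
        reduced = fit_initial_rates(points, substrate_inhibition=False)
        reduced.substrate_inhibition_detected = False
        return reduced

    return InitialRateFit(
        Vmax=Vmax,
        K_m=K_m,
        K_s=K_s,
        se_Vmax=Vmax * se_log[0],
        se_K_m=K_m * se_log[1],
        se_K_s=(K_s * se_log[2]) if (substrate_inhibition and K_s is not None) else None,
        converged=bool(best.success),
        chi2=chi2,
        substrate_inhibition_detected=detected,
    )
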