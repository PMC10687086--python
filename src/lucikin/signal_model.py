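"""Luminescence signal model: product trajectories <-> plate-reader intensity.

A luminometer reports relative light units (RLU) proportional to the photon
flux, itself proportional to the product-formation rate.  Over one read
window the instrument integrates photons, so intensity is modelled as the
*average* rate over the interval:

    I_i = f * (P(t_i) - P(t_{i-1})) / (t_i - t_{i-1})

with f the scaling factor in RLU·s per µM.  Accumulating I·Δt therefore
telescopes back to f·P(t), which is what makes progress-curve kinetics
possible in relative units: the cumulative ("conversion") curve is
proportional to product concentration, and total conversion of a known S0
pins down f without absolute photon-yield calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, FormatError, TruncationError
from .kinetic_core import ProgressCurve

__all__ = [
    "LuminescenceTrace",
    "ConversionCurve",
    "subtract_baseline",
    "intensity_from_progress",
    "cumulative_luminescence",
    "calibrate_scaling",
    "specific_activity",
    "relative_activity",
]

logger = logging.getLogger(__name__)

#: stop criterion: recording ends once intensity falls below this fraction of max
COMPLETION_INTENSITY_FRACTION = 0.005
#: specific-activity monitoring window, s
ACTIVITY_WINDOW_S = 15.0
#: allowed drift of intensity across the activity window before flagging
ACTIVITY_STABILITY_TOL = 0.02


@dataclass
class LuminescenceTrace:
    """Raw (or baseline-corrected) intensity series for one well."""

    times: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape or self.times.ndim != 1:
            raise FormatError("times and intensity must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("trace times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.times.shape:
                raise FormatError("sigma must match times in length")
            if np.any(self.sigma <= 0):
                raise FormatError("sigma must be strictly positive where provided")


@dataclass
class ConversionCurve:
    """Cumulative luminescence vs time; µM once calibrated by scaling_f."""

    times: np.ndarray
    cumulative: np.ndarray
    sigma: np.ndarray | None = None
    scaling_f: float | None = None
    calibrated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.calibrated and self.scaling_f is None:
            raise DomainError("calibrated curve requires scaling_f")


def subtract_baseline(trace: LuminescenceTrace, baseline_s: float = 10.0) -> LuminescenceTrace:
    """Remove the pre-injection background and shift t=0 to the injection.

    Background is the median intensity over the first ``baseline_s`` seconds.
    Post-subtraction negative intensities are clipped at zero; the clip count
    is logged and recorded in ``meta['n_clipped']``.
    """
    pre = trace.times < baseline_s
    post = ~pre
    if not np.any(post):
        raise FormatError("trace contains no post-injection reads")
    background = float(np.median(trace.intensity[pre])) if np.any(pre) else 0.0
    corrected = trace.intensity[post] - background
    n_clipped = int(np.sum(corrected < 0))
    if n_clipped:
        logger.info("baseline subtraction clipped %d negative intensities", n_clipped)
    corrected = np.maximum(corrected, 0.0)
    meta = dict(trace.meta)
    meta.update(background_rlu=background, n_clipped=n_clipped, baseline_subtracted=True)
    return LuminescenceTrace(
        times=trace.times[post] - baseline_s,
        intensity=corrected,
        sigma=None if trace.sigma is None else trace.sigma[post],
        meta=meta,
    )


def intensity_from_progress(
    curve: ProgressCurve, scaling_f: float, read_interval_s: float | None = None
) -> LuminescenceTrace:
    """Forward signal model: difference-quotient intensity from a product curve.

    If ``read_interval_s`` differs from the curve grid the product trajectory
    is resampled by interpolation (logged).  Injection is at t = 0; the first
    interval runs from 0 (P = 0) to the first read.
    """
    if not scaling_f > 0:
        raise DomainError("scaling_f must be positive")
    t, P = curve.times, curve.product
    if read_interval_s is not None:
        dt = np.diff(t, prepend=0.0)
        if not np.allclose(dt, read_interval_s, rtol=1e-9, atol=1e-12):
            n = int(np.floor(t[-1] / read_interval_s + 1e-9))
            t_new = read_interval_s * np.arange(1, n + 1)
            logger.info(
                "resampling progress curve from native grid to read interval %.4g s",
                read_interval_s,
            )
            P = np.interp(t_new, t, P)
            t = t_new
    dt = np.diff(t, prepend=0.0)
    I = scaling_f * np.diff(P, prepend=0.0) / dt
    meta = {"S0_uM": curve.S0, "E0_uM": curve.E0, "scaling_f": scaling_f}
    return LuminescenceTrace(times=t, intensity=I, meta=meta)


def cumulative_luminescence(trace: LuminescenceTrace) -> ConversionCurve:
    """Transform an intensity trace into cumulative luminescence (RLU·s).

    Left-rectangle accumulation C_i = Σ_{j<=i} I_j·Δt_j with the first
    interval anchored at the injection (t = 0).  Expects a baseline-trimmed
    trace.  Per-point uncertainties propagate as the running root sum of
    squares of I·Δt uncertainties.
    """
    dt = np.diff(trace.times, prepend=0.0)
    if np.any(dt <= 0):
        raise FormatError("non-monotone or non-positive time steps in trace")
    cumulative = np.cumsum(trace.intensity * dt)
    sigma = None
    if trace.sigma is not None:
        sigma = np.sqrt(np.cumsum((trace.sigma * dt) ** 2))
        sigma = np.maximum(sigma, np.finfo(float).tiny)
    return ConversionCurve(
        times=trace.times.copy(), cumulative=cumulative, sigma=sigma, meta=dict(trace.meta)
    )


def completion_fraction_of_max_rate(curve: ConversionCurve) -> float:
    """Final signal rate as a fraction of the maximal rate (completion proxy)."""
    if curve.times.size < 3:
        raise DomainError("curve too short to assess completion")
    rates = np.diff(curve.cumulative) / np.diff(curve.times)
    max_rate = float(np.max(rates))
    if max_rate <= 0:
        return 0.0
    return float(rates[-1] / max_rate)


def calibrate_scaling(
    curve: ConversionCurve,
    S0: float,
    conversion_threshold: float = 0.995,
    override_completion: bool = False,
) -> float:
    """Scaling factor f = plateau cumulative / S0 from a complete-conversion curve.

    The curve must have run to the completion criterion (final rate below
    0.5% of the maximal rate, mirroring the instrument stop rule) unless
    ``override_completion`` is set.
    """
    if not S0 > 0:
        raise DomainError("S0 must be positive")
    ratio = completion_fraction_of_max_rate(curve)
    if ratio > COMPLETION_INTENSITY_FRACTION and not override_completion:
        # crude conversion estimate assuming the plateau would be ~S0*f
        raise TruncationError(
            f"curve did not reach completion (final/max signal rate = {ratio:.3g} "
            f"> {COMPLETION_INTENSITY_FRACTION}); pass override_completion=True to force",
            achieved_fraction=ratio,
        )
    return float(curve.cumulative[-1] / S0)


def apply_scaling(curve: ConversionCurve, scaling_f: float, S0: float | None = None) -> ConversionCurve:
    """Return a calibrated copy of ``curve`` in µM product units."""
    if not scaling_f > 0:
        raise DomainError("scaling_f must be positive")
    out = ConversionCurve(
        times=curve.times.copy(),
        cumulative=curve.cumulative / scaling_f,
        sigma=None if curve.sigma is None else curve.sigma / scaling_f,
        scaling_f=scaling_f,
        calibrated=True,
        meta=dict(curve.meta),
    )
    if S0 is not None and out.cumulative[-1] > S0 * 1.05:
        raise DomainError(
            f"calibrated curve exceeds S0 by more than 5% "
            f"(terminal {out.cumulative[-1]:.4g} µM vs S0 {S0:.4g} µM)"
        )
    return out


def specific_activity(trace: LuminescenceTrace, E0_uM: float) -> tuple[float, bool]:
    """Specific activity in RLU·s⁻¹·M⁻¹ with a 2% stability flag.

    Activity is the mean baseline-corrected intensity over the first 15 s
    after injection, divided by the molar enzyme concentration.  The flag is
    False when the intensity at 15 s deviates more than 2% from the starting
    intensity (enzyme-limited linear regime violated).
    """
    if E0_uM <= 0:
        raise DomainError("E0 must be strictly positive")
    mask = trace.times <= ACTIVITY_WINDOW_S + 1e-9
    if not np.any(mask) or trace.times[mask][-1] < ACTIVITY_WINDOW_S - 1e-9:
        raise DomainError("trace must cover at least 15 s post-injection")
    window = trace.intensity[mask]
    activity = float(np.mean(window)) / (E0_uM * 1e-6)
    start, end = window[0], window[-1]
    stable = bool(start > 0 and abs(end / start - 1.0) <= ACTIVITY_STABILITY_TOL)
    return activity, stable


def relative_activity(
    activities: Mapping[str, float], reference_variant: str
) -> dict[str, float]:
    """Activities as percent of a reference variant (reference = 100%)."""
    if reference_variant not in activities:
        raise DomainError(f"reference variant {reference_variant!r} missing")
    ref = activities[reference_variant]
    if not ref > 0:
        raise DomainError("reference activity must be strictly positive")
    return {k: 100.0 * v / ref for k, v in activities.items()}
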