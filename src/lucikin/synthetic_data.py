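"""Synthetic plate-reader luminescence datasets with known ground truth.

Emulates an injection-triggered luminometer run: 10 s of baseline reads at
the background level, injection at t = baseline_s, then sampling at a fixed
read interval until the (median-smoothed) signal drops below 0.5% of its
running maximum — i.e. the substrate is spent — or until the 1000 s cap.

Noise is Gaussian, proportional + additive on intensity:

    I_obs = I_true + N(0, sigma),   sigma² = (cv·I_true)² + additive_sd²

and sigma is recorded per point, so sigma-normalized residuals are exactly
unit-scaled under the generating truth.  Real instruments additionally show
injector mixing artifacts, well-to-well crosstalk and detector drift, none
of which are modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DomainError
from .kinetic_core import AssayConditions, KineticParams, KineticScheme, integrate_progress
from .signal_model import (
    COMPLETION_INTENSITY_FRACTION,
    LuminescenceTrace,
    intensity_from_progress,
)

__all__ = [
    "NoiseModel",
    "SeriesDesign",
    "StudyEntry",
    "StudyBundle",
    "design_concentration_series",
    "generate_trace",
    "jitter_concentrations",
    "generate_study",
]

DEFAULT_BACKGROUND_RLU = 100.0
DEFAULT_SCALING_F = 1.0e6  # RLU·s per µM
#: stop-rule smoothing window (reads); odd, median
SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise law for synthetic intensities."""

    proportional_cv: float = 0.02
    additive_sd: float = 5.0  # RLU
    seed: int = 0

    def __post_init__(self):
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise DomainError("noise magnitudes must be nonnegative")

    def sigma(self, true_intensity: np.ndarray) -> np.ndarray:
        s = np.sqrt((self.proportional_cv * true_intensity) ** 2 + self.additive_sd**2)
        # zero-noise generator: keep sigma usable as unit weights
        return np.where(s > 0, s, 1.0)


@dataclass(frozen=True)
class SeriesDesign:
    """Substrate concentration series as multiples of K_m, with replicates."""

    multipliers: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    replicates: int = 3

    def __post_init__(self):
        if any(m <= 0 for m in self.multipliers):
            raise DomainError("multipliers must be strictly positive")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")


def design_concentration_series(K_m: float, design: SeriesDesign = SeriesDesign()) -> list[float]:
    """Substrate series S0_i = multiplier_i · K_m, ascending, µM."""
    if not K_m > 0:
        raise DomainError("K_m must be positive")
    return sorted(m * K_m for m in design.multipliers)


def jitter_concentrations(
    values: Sequence[float], max_fraction: float = 0.05, seed: int = 0
) -> list[float]:
    """Perturb each concentration by a uniform factor within ±max_fraction."""
    if max_fraction < 0:
        raise DomainError("max_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - max_fraction, 1.0 + max_fraction, size=len(values))
    return [v * f for v, f in zip(values, factors)]


def _moving_median(x: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    if x.size == 0 or window <= 1:
        return x
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, window)
    return np.median(view, axis=1)


def _stop_index(signal: np.ndarray) -> int | None:
    """First read where the smoothed signal drops under 0.5% of its running max."""
    smooth = _moving_median(signal)
    running_max = np.maximum.accumulate(smooth)
    below = smooth < COMPLETION_INTENSITY_FRACTION * running_max
    # ignore the very first reads where the running max is still forming
    below[: SMOOTH_WINDOW] = False
    idx = np.flatnonzero(below)
    return int(idx[0]) if idx.size else None


def generate_trace(
    params: KineticParams,
    cond: AssayConditions,
    scheme: KineticScheme = KineticScheme(),
    scaling_f: float = DEFAULT_SCALING_F,
    noise: NoiseModel = NoiseModel(),
    background_rlu: float = DEFAULT_BACKGROUND_RLU,
    rng: np.random.Generator | None = None,
    meta: Mapping | None = None,
) -> LuminescenceTrace:
    """Simulate one raw well trace: baseline + injection + stop rule.

    Times are absolute from recording start; injection occurs at
    ``cond.baseline_s``.  ``rng`` overrides the noise model's seed (used by
    :func:`generate_study` to give every well an independent substream).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    dt = cond.read_interval_s
    n_base = int(np.floor(cond.baseline_s / dt + 1e-9))
    t_base = dt * np.arange(n_base)
    post = cond.read_times()

    if cond.E0 > 0:
        progress = integrate_progress(params, cond, scheme, times=post)
        signal = intensity_from_progress(progress, scaling_f).intensity
    else:
        signal = np.zeros_like(post)

    true_base = np.full(n_base, background_rlu)
    true_post = background_rlu + signal
    mu = np.concatenate([true_base, true_post])
    sigma = noise.sigma(mu)
    noisy = mu + (rng.standard_normal(mu.size) * sigma
                  if (noise.proportional_cv > 0 or noise.additive_sd > 0) else 0.0)

    # stop rule operates on the background-free post-injection signal
    observed_signal = noisy[n_base:] - background_rlu
    stop = _stop_index(observed_signal)
    completed = stop is not None
    end = n_base + (stop + 1 if completed else post.size)

    times = np.concatenate([t_base, cond.baseline_s + post])[:end]
    full_meta = {
        "read_interval_s": dt,
        "baseline_s": cond.baseline_s,
        "background_rlu": background_rlu,
        "E0_uM": cond.E0,
        "S0_uM": cond.S0,
        "scaling_f_true": scaling_f,
        "completed": completed,
    }
    if meta:
        full_meta.update(meta)
    return LuminescenceTrace(times=times, intensity=noisy[:end], sigma=sigma[:end], meta=full_meta)


@dataclass(frozen=True)
class StudyEntry:
    """One enzyme–luciferin pair to be measured across the series."""

    variant: str
    luciferin: str
    params: KineticParams
    scaling_f: float = DEFAULT_SCALING_F


@dataclass
class StudyBundle:
    """Generated traces plus the machine-readable generating truth."""

    traces: list[LuminescenceTrace]
    truth: dict


def generate_study(
    entries: Sequence[StudyEntry],
    design: SeriesDesign = SeriesDesign(),
    noise: NoiseModel = NoiseModel(),
    E0: float = 0.01,
    scheme: KineticScheme = KineticScheme(),
    read_interval_s: float = 0.5,
    max_duration_s: float = 1000.0,
    baseline_s: float = 10.0,
    background_rlu: float = DEFAULT_BACKGROUND_RLU,
    jitter_fraction: float = 0.0,
    include_calibration: bool = False,
    calibration_E0: float = 10.0,
) -> StudyBundle:
    """Full kinetic study: every entry × concentration series × replicates.

    With ``jitter_fraction`` > 0 the true dispensed concentrations deviate
    from nominal by up to that fraction (uniform), mimicking pipetting
    fluctuation; nominal values are what the downstream fit sees.  With
    ``include_calibration`` each entry also gets one excess-enzyme well at
    the lowest S0, run to total conversion, for scaling-factor calibration.
    """
    keys = [(e.variant, e.luciferin) for e in entries]
    if len(set(keys)) != len(keys):
        raise ConfigError("duplicate (variant, luciferin) entries in study")

    root = np.random.SeedSequence(noise.seed)
    traces: list[LuminescenceTrace] = []
    truth_entries = {}
    stream = iter(root.spawn(len(entries) * (len(design.multipliers) * design.replicates + 1)))

    for entry in entries:
        series = design_concentration_series(entry.params.K_m, design)
        per_curve_truth = []
        for S0 in series:
            for rep in range(1, design.replicates + 1):
                ss = next(stream)
                rng = np.random.default_rng(ss)
                S0_true, E0_true = S0, E0
                if jitter_fraction > 0:
                    jrng = np.random.default_rng(ss.spawn(1)[0])
                    S0_true = S0 * jrng.uniform(1 - jitter_fraction, 1 + jitter_fraction)
                cond = AssayConditions(
                    E0=E0_true, S0=S0_true, baseline_s=baseline_s,
                    read_interval_s=read_interval_s, max_duration_s=max_duration_s,
                )
                trace = generate_trace(
                    entry.params, cond, scheme, entry.scaling_f, noise,
                    background_rlu, rng,
                    meta={
                        "variant": entry.variant, "luciferin": entry.luciferin,
                        "replicate": rep, "S0_uM": S0, "E0_uM": E0,
                        "S0_true_uM": S0_true, "E0_true_uM": E0_true,
                        "is_calibration": False,
                    },
                )
                traces.append(trace)
                per_curve_truth.append({"S0_nominal": S0, "S0_true": S0_true, "replicate": rep})
        if include_calibration:
            ss = next(stream)
            cond = AssayConditions(
                E0=calibration_E0, S0=min(series), baseline_s=baseline_s,
                read_interval_s=read_interval_s, max_duration_s=max_duration_s,
            )
            traces.append(
                generate_trace(
                    entry.params, cond, scheme, entry.scaling_f, noise,
                    background_rlu, np.random.default_rng(ss),
                    meta={
                        "variant": entry.variant, "luciferin": entry.luciferin,
                        "replicate": 1, "S0_uM": min(series), "E0_uM": calibration_E0,
                        "S0_true_uM": min(series), "E0_true_uM": calibration_E0,
                        "is_calibration": True,
                    },
                )
            )
        truth_entries[f"{entry.variant}|{entry.luciferin}"] = {
            "k_cat": entry.params.k_cat,
            "K_m": entry.params.K_m,
            "K_p": entry.params.K_p,
            "K_s": entry.params.K_s,
            "scaling_f": entry.scaling_f,
            "curves": per_curve_truth,
        }

    truth = {
        "entries": truth_entries,
        "design": {"multipliers": list(design.multipliers), "replicates": design.replicates},
        "noise": {
            "proportional_cv": noise.proportional_cv,
            "additive_sd": noise.additive_sd,
            "seed": noise.seed,
        },
        "E0_uM": E0,
        "read_interval_s": read_interval_s,
        "max_duration_s": max_duration_s,
        "baseline_s": baseline_s,
        "background_rlu": background_rlu,
        "jitter_fraction": jitter_fraction,
        "scheme": scheme.scheme_id.value,
    }
    return StudyBundle(traces=traces, truth=truth)
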