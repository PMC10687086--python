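"""File formats, run configuration and the two-stage pipeline.

Data interchange is deliberately plain: RFC-4180 CSV (UTF-8, decimal point,
comma separator) for traces and velocity tables — the dialect plate-reader
exports and spreadsheets share — and JSON for configuration, ground truth
and fit results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, TruncationError
from .global_fit import FitOptions, datasets_from_traces, fit_global
from .initial_rate import fit_initial_rates, initial_velocity
from .kinetic_core import KineticParams, KineticScheme
from .signal_model import (
    LuminescenceTrace,
    calibrate_scaling,
    cumulative_luminescence,
    subtract_baseline,
)
from .synthetic_data import NoiseModel, SeriesDesign, StudyBundle, StudyEntry, generate_study
from .uncertainty import specificity_constant

__all__ = [
    "TRACE_COLUMNS",
    "read_trace_csv",
    "write_trace_csv",
    "read_truth_json",
    "write_truth_json",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["time_s", "intensity_rlu", "variant", "luciferin", "E0_uM", "S0_uM", "replicate"]
OPTIONAL_COLUMNS = ["sigma_rlu", "is_calibration", "baseline_s", "read_interval_s"]


def write_trace_csv(traces: list[LuminescenceTrace], path) -> None:
    """Write traces in long format, one row per read."""
    frames = []
    for tr in traces:
        m = tr.meta
        df = pd.DataFrame(
            {
                "time_s": tr.times,
                "intensity_rlu": tr.intensity,
                "sigma_rlu": tr.sigma if tr.sigma is not None else np.nan,
                "variant": m.get("variant", ""),
                "luciferin": m.get("luciferin", ""),
                "E0_uM": m.get("E0_uM", np.nan),
                "S0_uM": m.get("S0_uM", np.nan),
                "replicate": m.get("replicate", 1),
                "is_calibration": m.get("is_calibration", False),
                "baseline_s": m.get("baseline_s", 10.0),
                "read_interval_s": m.get("read_interval_s", np.nan),
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path) -> list[LuminescenceTrace]:
    """Parse a trace CSV back into per-well traces (grouped by metadata)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    has_cal = "is_calibration" in df.columns
    keys = ["variant", "luciferin", "S0_uM", "E0_uM", "replicate"] + (
        ["is_calibration"] if has_cal else []
    )
    traces = []
    for key, g in df.groupby(keys, sort=True):
        g = g.reset_index(drop=True)
        t = g["time_s"].to_numpy(float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise FormatError(f"non-monotone time at row {int(g.index[bad[0] + 1])} of well {key}")
        sigma = None
        if "sigma_rlu" in g.columns and g["sigma_rlu"].notna().all():
            sigma = g["sigma_rlu"].to_numpy(float)
        meta = {
            "variant": str(g["variant"].iloc[0]),
            "luciferin": str(g["luciferin"].iloc[0]),
            "E0_uM": float(g["E0_uM"].iloc[0]),
            "S0_uM": float(g["S0_uM"].iloc[0]),
            "replicate": int(g["replicate"].iloc[0]),
            "is_calibration": bool(g["is_calibration"].iloc[0]) if has_cal else False,
        }
        if "baseline_s" in g.columns:
            meta["baseline_s"] = float(g["baseline_s"].iloc[0])
        if "read_interval_s" in g.columns and pd.notna(g["read_interval_s"].iloc[0]):
            meta["read_interval_s"] = float(g["read_interval_s"].iloc[0])
        traces.append(LuminescenceTrace(times=t, intensity=g["intensity_rlu"].to_numpy(float),
                                        sigma=sigma, meta=meta))
    return traces


def write_truth_json(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "seed", "scheme", "design", "noise", "simulate", "input_csv", "fit",
    "contours", "output_dir",
}
_SIM_KEYS = {"entries", "E0", "read_interval_s", "max_duration_s", "baseline_s",
             "background_rlu", "jitter_fraction", "include_calibration", "calibration_E0"}
_FIT_KEYS = {"multistart_n", "fit_Ks", "fit_conc_corrections", "observable"}
_CONTOUR_KEYS = {"pair", "grid_n", "span", "confidence"}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration; every stochastic step is seeded."""

    seed: int
    scheme: str = "mm_prod_inhib"
    design: SeriesDesign = SeriesDesign()
    noise: NoiseModel = NoiseModel()
    simulate: dict | None = None
    input_csv: str | None = None
    fit: dict = field(default_factory=dict)
    contours: dict | None = None
    output_dir: str = "lucikin_out"


def load_config(source) -> RunConfig:
    """Build a RunConfig from a dict or a YAML/JSON file; unknown keys rejected."""
    if isinstance(source, (str, Path)):
        import yaml

        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("configuration must set a seed (all randomness flows from it)")
    if raw.get("simulate") is None and raw.get("input_csv") is None:
        raise ConfigError("configuration needs either 'simulate' or 'input_csv'")
    sim = raw.get("simulate")
    if sim is not None:
        bad = set(sim) - _SIM_KEYS
        if bad:
            raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
    bad = set(raw.get("fit", {})) - _FIT_KEYS
    if bad:
        raise ConfigError(f"unknown fit keys: {sorted(bad)}")
    if raw.get("contours") is not None:
        bad = set(raw["contours"]) - _CONTOUR_KEYS
        if bad:
            raise ConfigError(f"unknown contour keys: {sorted(bad)}")
    design = SeriesDesign(**{k: tuple(v) if k == "multipliers" else v
                             for k, v in raw.get("design", {}).items()})
    noise_kw = dict(raw.get("noise", {}))
    noise_kw.setdefault("seed", raw["seed"])
    return RunConfig(
        seed=int(raw["seed"]),
        scheme=raw.get("scheme", "mm_prod_inhib"),
        design=design,
        noise=NoiseModel(**noise_kw),
        simulate=sim,
        input_csv=raw.get("input_csv"),
        fit=dict(raw.get("fit", {})),
        contours=raw.get("contours"),
        output_dir=raw.get("output_dir", "lucikin_out"),
    )


def _simulate_from_config(config: RunConfig) -> StudyBundle:
    sim = dict(config.simulate)
    entries = [
        StudyEntry(
            variant=e["variant"],
            luciferin=e["luciferin"],
            params=KineticParams(
                k_cat=e["k_cat"], K_m=e["K_m"],
                K_p=e.get("K_p", float("inf")), K_s=e.get("K_s", float("inf")),
            ),
            scaling_f=e.get("scaling_f", 1.0e6),
        )
        for e in sim.pop("entries")
    ]
    return generate_study(entries, design=config.design, noise=config.noise,
                          scheme=KineticScheme(config.scheme), **sim)


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute initial-rate -> design check -> global fit -> derived quantities.

    Returns the report dict; writes JSON/CSV artifacts under ``output_dir``.
    Each enzyme–luciferin group in the input is fitted independently.  When
    no analytical curve in a group completes conversion, the scaling factor
    is fixed from that group's excess-enzyme calibration well (if present).
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "scheme": config.scheme, "decisions": []}

    if config.input_csv:
        traces = read_trace_csv(config.input_csv)
        log["input"] = str(config.input_csv)
    else:
        bundle = _simulate_from_config(config)
        traces = bundle.traces
        write_trace_csv(traces, out / "traces.csv")
        write_truth_json(bundle.truth, out / "truth.json")
        log["input"] = "simulated"

    scheme = KineticScheme(config.scheme)
    fit_kw = dict(config.fit)
    multistart_n = fit_kw.pop("multistart_n", 8)
    report: dict = {"groups": {}}

    groups: dict[str, list] = {}
    for tr in traces:
        key = f"{tr.meta.get('variant', '')}|{tr.meta.get('luciferin', '')}"
        groups.setdefault(key, []).append(tr)

    for key, group_traces in sorted(groups.items()):
        analytical = [t for t in group_traces if not t.meta.get("is_calibration")]
        calibration = [t for t in group_traces if t.meta.get("is_calibration")]

        # stage 1: initial velocities (relative units) and provisional K_m
        points = []
        for tr in analytical:
            if tr.meta.get("replicate", 1) != 1:
                continue
            curve = cumulative_luminescence(subtract_baseline(tr, tr.meta.get("baseline_s", 10.0)))
            try:
                points.append(initial_velocity(curve))
            except Exception as exc:
                logger.warning("initial velocity skipped for %s: %s", key, exc)
        stage1 = None
        if len(points) >= 3:
            stage1 = fit_initial_rates(points, substrate_inhibition=fit_kw.get("fit_Ks", False))
            log["decisions"].append(
                f"{key}: stage-1 K_m = {stage1.K_m:.4g} µM seeds the global fit"
            )

        datasets = datasets_from_traces(analytical)
        options = FitOptions(multistart_n=multistart_n, **fit_kw)

        # no completed curve: fix scaling from the excess-enzyme calibration well
        completed = any(t.meta.get("completed") for t in analytical)
        if not completed and calibration:
            cal_curve = cumulative_luminescence(
                subtract_baseline(calibration[0], calibration[0].meta.get("baseline_s", 10.0))
            )
            try:
                f_cal = calibrate_scaling(cal_curve, calibration[0].meta["S0_uM"])
                options = dataclasses.replace(options, fixed_scaling={key: f_cal})
                log["decisions"].append(
                    f"{key}: no curve completed; scaling fixed from calibration ({f_cal:.6g})"
                )
            except TruncationError as exc:
                log["decisions"].append(f"{key}: calibration unusable ({exc})")

        init = {"K_m": stage1.K_m} if stage1 is not None else None
        result = fit_global(datasets, scheme, init=init, seed=config.seed, options=options)

        spec = specificity_constant(
            result.params.k_cat, result.se.get("k_cat", 0.0),
            result.params.K_m, result.se.get("K_m", 0.0),
        )
        group_report = {
            "params": {
                "k_cat": result.params.k_cat, "K_m": result.params.K_m,
                "K_p": result.params.K_p if np.isfinite(result.params.K_p) else None,
                "K_s": result.params.K_s if np.isfinite(result.params.K_s) else None,
            },
            "se": result.se,
            "scaling_f": result.scaling_f,
            "conc_corrections": result.conc_corrections,
            "chi2": result.chi2,
            "n_points": result.n_points,
            "n_params": result.n_params,
            "converged": result.converged,
            "boundary_warnings": result.boundary_warnings,
            "specificity_constant": {"value": spec.value, "se": spec.se},
        }
        if stage1 is not None:
            group_report["stage1"] = {"K_m": stage1.K_m, "Vmax": stage1.Vmax,
                                      "se_K_m": stage1.se_K_m}
        report["groups"][key] = group_report

    report["log"] = log
    (out / "fit_result.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    rows = [
        {"group": k, **{p: v for p, v in g["params"].items()},
         "specificity": g["specificity_constant"]["value"],
         "specificity_se": g["specificity_constant"]["se"], "chi2": g["chi2"]}
        for k, g in report["groups"].items()
    ]
    pd.DataFrame(rows).to_csv(out / "derived_quantities.csv", index=False)
    return report
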