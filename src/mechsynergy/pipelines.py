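"""End-to-end analysis pipelines producing archivable report bundles.

Each runner takes a :class:`~mechsynergy.io.RunConfig`, resolves the limb
model (builtin generator or JSON file), executes the analysis, and writes
CSV/JSON outputs plus a ``summary.json`` that embeds the config, package
version, config hash, and per-stage timings — so a run is reproducible bit
for bit from its own output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError, SingularityError
from .feedback import EmgTransform, FeedbackSynergy
from .feedforward import FeedforwardSynergy, bootstrap_ci
from .io import BUILTIN_MODELS, RunConfig, emg_to_csv, validate_model
from .limb import LimbModel, endpoint_to_joint_delta
from .synthetic import (
    make_finger_like,
    make_leg_like,
    make_schematic_limb,
    perturbation_directions,
)

__all__ = ["resolve_model", "posture_grid", "run_feedback", "run_feedforward"]

log = logging.getLogger("mechsynergy")


def resolve_model(source: str) -> LimbModel:
    """A builtin model name or a path to a limb-model JSON file."""
    builtins = {
        "schematic": make_schematic_limb,
        "finger": lambda: make_finger_like("extended"),
        "finger-flexed": lambda: make_finger_like("flexed"),
        "leg": make_leg_like,
    }
    if source in builtins:
        return builtins[source]()
    if Path(source).exists():
        return validate_model(source)
    raise SchemaError(
        f"model source {source!r} is neither a builtin ({', '.join(BUILTIN_MODELS)}) "
        "nor an existing file"
    )


def posture_grid(
    model: LimbModel, extent: float, n_per_side: int
) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """Rectangular endpoint-space grid mapped to test postures.

    Endpoint offsets on an ``n x n`` grid spanning ``[-extent, extent]`` m in
    the plane (orientation held fixed) are mapped through linearized inverse
    kinematics, ``q = q0 + J^{-1} dx``.  Offsets whose mapping fails (e.g. a
    singular Jacobian) are skipped here; postures that are themselves
    singular are reported as excluded downstream.
    """
    offsets = np.linspace(-extent, extent, n_per_side)
    postures, grid_xy = [], []
    for ox in offsets:
        for oy in offsets:
            dx = np.zeros(model.n_endpoint_dofs)
            dx[0], dx[1] = ox, oy
            try:
                dq = endpoint_to_joint_delta(model, dx)
            except SingularityError:
                continue
            postures.append(model.posture + dq)
            grid_xy.append((float(ox), float(oy)))
    return postures, grid_xy


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_summary(outdir: Path, config: RunConfig, payload: dict, timings: dict) -> dict:
    summary = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        **payload,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def run_feedback(config: RunConfig) -> dict:
    """Feedback pipeline: simulated EMG, PCA curve, posture generalization map.

    Writes ``emg.csv``, ``vaf_curve.csv``, ``generalization_map.csv`` and
    ``summary.json`` into the configured output directory and returns the
    summary dict.
    """
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = resolve_model(config.model)
    log.info("feedback run: model=%s config_hash=%s", config.model, _config_hash(config))
    for key, value in config.to_dict().items():
        log.info("  param %s = %r", key, value)
    movements = perturbation_directions(
        config.k_directions, config.magnitude_m, model.n_endpoint_dofs
    )
    transform = EmgTransform(kind=config.transform, gain=config.gain)
    timings = {"setup": time.perf_counter() - t0}

    t1 = time.perf_counter()
    res = FeedbackSynergy(model, movements, transform).fit(threshold=config.threshold)
    emg_to_csv(res.emg, outdir / "emg.csv")
    cum = res.cumulative_variance()
    pd.DataFrame(
        {
            "component": np.arange(1, len(cum) + 1),
            "variance_ratio": res.basis.explained_variance_ratios,
            "cumulative": cum,
        }
    ).to_csv(outdir / "vaf_curve.csv", index=False)
    timings["fit"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    scale = float(np.sum(model.link_lengths)) if model.link_lengths is not None else 1.0
    postures, grid_xy = posture_grid(
        model, config.generalization_extent * scale, config.generalization_grid
    )
    reports, excluded = res.generalization_map(postures)
    rows, ri = [], 0
    for i, (x, y) in enumerate(grid_xy):
        if i in excluded:
            rows.append({"dx_m": x, "dy_m": y, "global_vaf": np.nan,
                         "min_muscle_vaf": np.nan, "generalizes": False, "excluded": True})
        else:
            rep = reports[ri]
            ri += 1
            rows.append({"dx_m": x, "dy_m": y, "global_vaf": rep.global_vaf,
                         "min_muscle_vaf": float(np.min(rep.per_muscle_vaf)),
                         "generalizes": rep.generalizes, "excluded": False})
    pd.DataFrame(rows).to_csv(outdir / "generalization_map.csv", index=False)
    timings["generalization"] = time.perf_counter() - t2

    n_ok = sum(1 for r in reports if r.generalizes)
    payload = {
        "analysis": "feedback",
        "n_muscles": model.n_muscles,
        "n_components": res.n_components,
        "n_components_generalizing": res.n_components_generalizing,
        "cumulative_vaf": [float(c) for c in cum],
        "generalization_fraction": (n_ok / len(reports)) if reports else None,
        "n_test_postures": len(reports),
        "n_excluded_postures": len(excluded),
    }
    log.info("feedback done: n_components=%d", res.n_components)
    return _write_summary(outdir, config, payload, timings)


def run_feedforward(config: RunConfig) -> dict:
    """Feedforward pipeline: force scan, vertex enumeration, pooled PCA.

    Writes ``vertex_counts.csv``, ``vaf_curves.csv`` and ``summary.json``;
    an infeasible scan produces an empty (but valid) summary with a warning
    rather than an error.
    """
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = resolve_model(config.model)
    log.info("feedforward run: model=%s config_hash=%s", config.model, _config_hash(config))
    for key, value in config.to_dict().items():
        log.info("  param %s = %r", key, value)
    timings = {"setup": time.perf_counter() - t0}

    t1 = time.perf_counter()
    ff = FeedforwardSynergy(
        model,
        k_directions=config.k_directions,
        increment=config.increment_N,
        zero_components=config.zero_components,
    )
    res = ff.fit(threshold=config.threshold, per_level=False)
    timings["fit"] = time.perf_counter() - t1

    sol = res.solution_pca
    if sol is None or len(sol.levels) == 0:
        log.warning("empty feasible scan: no force level fits in every direction")
        pd.DataFrame(columns=["level_N", "n_vertices", "n_components"]).to_csv(
            outdir / "vertex_counts.csv", index=False
        )
        pd.DataFrame(columns=["level_N", "component", "cumulative_vaf"]).to_csv(
            outdir / "vaf_curves.csv", index=False
        )
        payload = {
            "analysis": "feedforward",
            "n_muscles": ff.action.n_muscles,
            "levels_N": [],
            "n_components_per_level": [],
            "pooled_n_components": None,
            "empty_scan": True,
        }
        return _write_summary(outdir, config, payload, timings)

    pd.DataFrame(
        {"level_N": sol.levels, "n_vertices": sol.n_vertices, "n_components": sol.n_components}
    ).to_csv(outdir / "vertex_counts.csv", index=False)
    curve_rows = []
    for lev, cum in zip(sol.levels, sol.cumulative_vaf):
        for i, c in enumerate(cum):
            curve_rows.append({"level_N": lev, "component": i + 1, "cumulative_vaf": c})
    pd.DataFrame(curve_rows).to_csv(outdir / "vaf_curves.csv", index=False)

    ci = None
    if len(sol.n_components) >= 2:
        ci = bootstrap_ci(np.asarray(sol.n_components, float), seed=config.seed)
    payload = {
        "analysis": "feedforward",
        "n_muscles": ff.action.n_muscles,
        "levels_N": [float(l) for l in sol.levels],
        "n_components_per_level": [int(k) for k in sol.n_components],
        "pooled_n_components": sol.pooled_n_components,
        "mean_n_components_ci95": ci,
        "empty_scan": False,
    }
    log.info("feedforward done: levels=%d max components=%s",
             len(sol.levels), max(sol.n_components))
    return _write_summary(outdir, config, payload, timings)
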