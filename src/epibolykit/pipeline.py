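"""End-to-end pipeline: simulate, render, detect, track, map, score.

``run_pipeline`` wires the stages together from a single configuration
dict, fanning one global seed out to independent per-stage substreams
so each stage is individually reproducible.  It writes the stage
tables (TSV), optional stacks (TIFF + sidecar) and a machine-readable
JSON run report with per-stage record counts; the same configuration
and seed produce byte-identical tables.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cartography import (
    EmbryoAxes,
    density_table,
    epiboly_percentage,
    unwrap_density,
)
from .detection import DetectionParams, detect_nuclei
from .io import write_config, write_stack, write_table
from .records import tracks_to_table
from .synthetic import RenderConfig, SimulationConfig, render_stack, simulate_epiboly
from .tracking import TrackingParams, track_nuclei

STAGE_NAMES = ("simulate", "render", "detect", "track", "density", "epiboly")


def stage_seeds(seed: int) -> dict[str, np.random.Generator]:
    """Fan a global seed out to named, independent per-stage streams."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGE_NAMES))
    return {name: np.random.default_rng(c) for name, c in zip(STAGE_NAMES, children)}


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages and write tables plus a run report.

    ``config`` keys (all optional, with defaults): ``seed``,
    ``simulation`` (SimulationConfig fields), ``render`` (RenderConfig
    fields plus ``enabled`` and ``frames``), ``detection``
    (DetectionParams fields), ``tracking`` (TrackingParams fields),
    ``density_radius_um``, ``grid`` (n_azimuth/n_elevation).
    Any stage failure raises with the stage name and cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rngs = stage_seeds(seed)
    report: dict = {
        "package": "epibolykit",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "stages": {},
    }

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------
    sim_cfg = SimulationConfig(**config.get("simulation", {}))
    if "rng_seed" not in config.get("simulation", {}):
        sim_cfg.rng_seed = int(rngs["simulate"].integers(2**31 - 1))
    truth = _stage("simulate", lambda: simulate_epiboly(sim_cfg))
    write_table(truth.nuclei, out / "ground_truth_nuclei.tsv")
    report["stages"]["simulate"] = {
        "n_records": int(len(truth.nuclei)),
        "n_frames": int(sim_cfg.n_frames),
        "final_margin_deg": float(truth.margin_polar_angle[-1]),
    }

    # --- render + detect (optional; heavy) ----------------------------
    render_cfg_dict = dict(config.get("render", {}))
    render_enabled = render_cfg_dict.pop("enabled", False)
    render_frames = render_cfg_dict.pop("frames", [0])
    detections = truth.nuclei
    if render_enabled:
        render_cfg = RenderConfig(**render_cfg_dict)
        det_params = DetectionParams(**config.get("detection", {}))
        det_tables = []
        for k in render_frames:
            frame_nuclei = truth.frame(int(k))
            stack = _stage(
                "render", lambda fn=frame_nuclei: render_stack(fn, render_cfg, rngs["render"])
            )
            write_stack(stack, out / f"stack_f{int(k):03d}.tif")
            det = _stage("detect", lambda s=stack, k=k: detect_nuclei(s, det_params, frame=int(k)))
            det_tables.append(det)
        detections = pd.concat(det_tables, ignore_index=True) if det_tables else truth.nuclei
        write_table(detections, out / "detections.tsv")
        report["stages"]["render"] = {"n_stacks": len(render_frames)}
        report["stages"]["detect"] = {"n_records": int(len(detections))}

    # --- track --------------------------------------------------------
    track_params = TrackingParams(**config.get("tracking", {}))
    track_source = truth.nuclei  # tracking runs on the full time series
    tracks = _stage("track", lambda: track_nuclei(track_source, track_params))
    track_table = tracks_to_table(tracks)
    write_table(track_table, out / "tracks.tsv")
    report["stages"]["track"] = {
        "n_tracks": len(tracks),
        "n_records": int(len(track_table)),
    }

    # --- density / unwrap ---------------------------------------------
    radius = float(config.get("density_radius_um", 40.0))
    grid_spec = config.get("grid", {})
    last = truth.frame(sim_cfg.n_frames - 1)
    dens = _stage("density", lambda: density_table(last, radius_um=radius))
    write_table(dens, out / "density.tsv")
    grid, az_edges, el_edges = unwrap_density(
        dens,
        n_azimuth=int(grid_spec.get("n_azimuth", 36)),
        n_elevation=int(grid_spec.get("n_elevation", 18)),
    )
    np.savetxt(out / "density_grid.tsv", grid, delimiter="\t")
    report["stages"]["density"] = {
        "n_records": int(len(dens)),
        "mean_count": float(dens["count"].mean()),
        "radius_um": radius,
    }

    # --- epiboly ------------------------------------------------------
    axes = EmbryoAxes(
        center=np.zeros(3),
        animal_pole=truth.animal_pole,
        vegetal_pole=truth.vegetal_pole,
    )
    margin_nucleus = last.loc[last["y_um"].idxmax()] if len(last) else None
    if margin_nucleus is not None:
        margin_point = margin_nucleus[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        pct = _stage("epiboly", lambda: epiboly_percentage(axes, margin_point))
        report["stages"]["epiboly"] = {"epiboly_pct": float(pct)}

    write_config({"simulation": asdict(sim_cfg)}, out / "resolved_config.json")
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
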