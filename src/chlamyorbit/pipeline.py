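"""Pipeline orchestration: simulate → track → analyze → model.

Each stage reads the previous stage's artifact from ``out_dir`` and writes
its own, so any suffix of the pipeline can be re-run (e.g. ``model`` alone
on an existing kinematics CSV). Artifacts are deterministic for a fixed
seed: running the same config twice produces byte-identical files. Every
JSON artifact carries a provenance block (config hash, package version,
seed, thresholds in force).

Artifacts
---------
``tracks_true.csv``
    Simulated ground-truth tracks (shared CSV dialect).
``stack.tif`` + ``truth_px.csv``
    Rendered image stack and per-frame pixel ground truth (render mode).
``tracks.csv``
    Tracks entering the analysis: recovered from the stack in render mode,
    otherwise the simulated tracks verbatim.
``kinematics.csv`` / ``summary.json``
    Per-cell estimates and the population summary.
``report.json``
    Force-model report for the population mean kinematics.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .kinematics import analyze_tracks, summarize_population
from .stokes import (CellGeometry, CellKinematics, FluidParams, end_to_end)
from .synthetic import (OrbitParams, RenderParams, TranslatorParams,
                        generate_orbit_track, generate_translator_track,
                        render_stack, write_stack, read_stack)
from .tracking import track_stack
from .tracks import Track, read_tracks, write_tracks

STAGES = ("simulate", "track", "analyze", "model")

logger = logging.getLogger("chlamyorbit")


def _log(stage: str, message: str) -> None:
    # stage-tagged lines to stderr; artifacts never mix with logs
    logger.info("%s: %s", stage, message)


def _provenance(config: PipelineConfig) -> dict:
    return {
        "package": "chlamyorbit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "kinematics_thresholds": config.kinematics.model_dump(),
    }


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def simulate_population(config: PipelineConfig) -> list[Track]:
    """Generate the labelled synthetic population the config describes.

    Cells are anchored on a grid with ``spacing_um`` pitch; track ids are
    assigned revolving first, then translating, then immotile, so the
    ground-truth class of each id is recoverable from the config counts.
    Per-cell seeds derive from the config seed via ``np.random.SeedSequence``.
    """
    sim = config.simulate
    n_total = sim.n_revolving + sim.n_translating + sim.n_immotile
    seeds = np.random.SeedSequence(config.seed).generate_state(max(n_total, 1))
    rng = np.random.default_rng(config.seed)
    side = max(1, math.ceil(math.sqrt(max(n_total, 1))))
    tracks: list[Track] = []
    for i in range(n_total):
        anchor = ((i % side + 1) * sim.spacing_um,
                  (i // side + 1) * sim.spacing_um)
        seed = int(seeds[i] % (2 ** 31))
        if i < sim.n_revolving:
            params = OrbitParams(
                center=anchor, R=sim.R_um, omega=sim.omega_rad_s,
                phase0=float(rng.uniform(0, 2 * np.pi)),
                beat_freq=sim.beat_freq_hz, beat_amp=sim.beat_amp_um,
                noise_sigma=sim.noise_sigma_um, duration=sim.duration_s,
                frame_interval=sim.frame_interval_s)
            tracks.append(generate_orbit_track(params, seed, track_id=i))
        elif i < sim.n_revolving + sim.n_translating:
            # heading chosen to stay near the anchor cell-free corridor;
            # distance covered must stay modest relative to the grid pitch
            params = TranslatorParams(
                start=anchor, speed=sim.translator_speed_um_s,
                heading=float(rng.uniform(0, 2 * np.pi)),
                noise_sigma=sim.noise_sigma_um, duration=sim.duration_s,
                frame_interval=sim.frame_interval_s)
            tracks.append(generate_translator_track(params, seed, track_id=i))
        else:
            params = TranslatorParams(
                start=anchor, speed=0.0, noise_sigma=sim.noise_sigma_um,
                duration=sim.duration_s, frame_interval=sim.frame_interval_s)
            tracks.append(generate_translator_track(params, seed, track_id=i))
    return tracks


def _render_params_for(config: PipelineConfig,
                       tracks: Sequence[Track]) -> RenderParams:
    """Frame geometry sized to contain every track with a cell-radius margin."""
    sim = config.simulate
    r_px = sim.cell_radius_um / sim.pixel_size_um
    max_x = max(tr.x.max() for tr in tracks) / sim.pixel_size_um
    max_y = max(tr.y.max() for tr in tracks) / sim.pixel_size_um
    shape = (int(math.ceil(max_y + 2 * r_px + 4)),
             int(math.ceil(max_x + 2 * r_px + 4)))
    return RenderParams(image_size=shape, pixel_size=sim.pixel_size_um,
                        cell_radius=sim.cell_radius_um,
                        blur_sigma=sim.blur_sigma_px)


def run_pipeline(config: PipelineConfig,
                 stages: Sequence[str] = STAGES) -> dict[str, Path]:
    """Run the requested pipeline stages; returns the artifact paths.

    Raises ``FileNotFoundError`` naming the stage to run first when an
    upstream artifact is missing.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks_true": out / "tracks_true.csv",
        "stack": out / "stack.tif",
        "truth_px": out / "truth_px.csv",
        "tracks": out / "tracks.csv",
        "kinematics": out / "kinematics.csv",
        "summary": out / "summary.json",
        "report": out / "report.json",
    }
    render = config.simulate.render

    if "simulate" in stages:
        tracks = simulate_population(config)
        write_tracks(tracks, paths["tracks_true"])
        _log("simulate", f"wrote {len(tracks)} ground-truth tracks")
        if render:
            rp = _render_params_for(config, tracks)
            stack, truth = render_stack(tracks, rp)
            write_stack(stack, paths["stack"])
            truth.to_csv(paths["truth_px"], index=False, float_format="%.6f")
            _log("simulate", f"rendered {stack.shape[0]} frames "
                             f"{stack.shape[1]}x{stack.shape[2]} px")
        else:
            write_tracks(tracks, paths["tracks"])

    if "track" in stages and render:
        if not paths["stack"].exists():
            raise FileNotFoundError(
                f"{paths['stack']} missing: run the 'simulate' stage first")
        stack = read_stack(paths["stack"])
        tr_cfg = config.tracking
        tracks = track_stack(
            stack, config.simulate.pixel_size_um,
            config.simulate.frame_interval_s, method=tr_cfg.method,
            polarity=tr_cfg.polarity, threshold=tr_cfg.threshold,
            min_area=tr_cfg.min_area_px, max_area=tr_cfg.max_area_px,
            max_disp=tr_cfg.max_disp_um, max_gap=tr_cfg.max_gap)
        write_tracks(tracks, paths["tracks"])
        _log("track", f"recovered {len(tracks)} tracks from the stack")

    if "analyze" in stages:
        if not paths["tracks"].exists():
            raise FileNotFoundError(
                f"{paths['tracks']} missing: run the "
                f"'{'track' if render else 'simulate'}' stage first")
        tracks = read_tracks(paths["tracks"])
        kcfg = config.kinematics
        kins, classes = analyze_tracks(
            tracks, net_disp_thresh=kcfg.net_disp_thresh_um,
            circularity_thresh=kcfg.circularity_thresh,
            beat_prominence=kcfg.beat_prominence)
        kin_df = pd.DataFrame([{
            "track_id": k.track_id,
            "R_um": k.R,
            "omega_rad_s": k.omega,
            "direction": k.direction,
            "beat_freq_hz": k.beat_freq if k.beat_freq is not None else "",
            "fit_residual_um": k.fit_residual,
        } for k in kins])
        kin_df.to_csv(paths["kinematics"], index=False, float_format="%.6f")
        summary: dict = {
            "classes": {str(tid): cls for tid, cls in classes.items()},
            "n_revolving": sum(c == "revolving" for c in classes.values()),
            "n_translating": sum(c == "translating" for c in classes.values()),
            "n_immotile": sum(c == "immotile" for c in classes.values()),
            "provenance": _provenance(config),
        }
        if kins:
            pop = summarize_population(kins)
            summary["population"] = {
                "n_cells": pop.n_cells,
                "mean_R_um": pop.mean_R,
                "mean_omega_rad_s": pop.mean_omega,
            }
        _write_json(paths["summary"], summary)
        _log("analyze", f"{len(kins)} revolving cells analysed")

    if "model" in stages:
        if not paths["kinematics"].exists():
            raise FileNotFoundError(
                f"{paths['kinematics']} missing: run the 'analyze' stage first")
        kin_df = pd.read_csv(paths["kinematics"])
        kins = [CellKinematics(track_id=int(r.track_id), R=float(r.R_um),
                               omega=float(r.omega_rad_s),
                               direction=str(r.direction), center=(0.0, 0.0),
                               fit_residual=float(r.fit_residual_um))
                for r in kin_df.itertuples()]
        geom = CellGeometry(r=config.geometry.r_um * 1e-6,
                            alpha=math.radians(config.geometry.alpha_deg))
        fluid = FluidParams(eta=config.fluid.eta_pa_s)
        report = end_to_end(kins, geom, fluid,
                            provenance=_provenance(config))
        _write_json(paths["report"], report)
        _log("model", "wrote force-model report")

    return paths
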