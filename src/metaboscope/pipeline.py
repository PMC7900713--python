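"""Stage orchestration for the end-to-end synthetic demonstration run.

The demo pipeline chains simulate → quantify → kinetics: a wash-out/wash-in
cohort is simulated and rendered to two-channel TIFF stacks with label
masks; the quantify stage measures per-cell ratio traces back out of the
imagery; the kinetics stage decomposes each measured trace into consumption
and uptake.  Every output lands in the run directory with a checksum
manifest; rerunning with the same config and seed reproduces the checksums.

One global seed expands to per-stage seeds as ``SeedSequence([seed, stage_index])``
so stages can be rerun independently and reproducibly.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as mio
from .config import BiosensorModel, ScenarioConfig
from .fret import measure_cell_fret
from .kinetics import fit_one_phase_decay, uptake_rate
from .sim.imaging import render_movie
from .sim.traces import CellParams, simulate_cell_trace
from .trace import CellTrace, frame_to_traces, traces_to_frame

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1
KNOWN_STAGES = ("simulate", "quantify", "kinetics", "spatial")


class RunConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    stages: list[str] = Field(default_factory=lambda: ["simulate", "quantify", "kinetics"])
    seed: int = 0
    out_dir: str = "run"
    um_per_px: Optional[float] = None
    params: dict[str, dict] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        for s in self.stages:
            if s not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if "spatial" in self.stages and self.um_per_px is None:
            raise ValueError("um_per_px is required when the spatial stage is enabled")
        return self

    def stage_seed(self, stage: str) -> int:
        idx = self.stages.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate", {})
    n_cells = int(p.get("n_cells", 12))
    washout = float(p.get("washout_min", 10.0))
    washin = float(p.get("washin_min", 40.0))
    duration = float(p.get("duration_min", 70.0))
    shape = tuple(p.get("image_shape", (160, 160)))
    seed = cfg.stage_seed("simulate")
    scen = ScenarioConfig(
        n_cells=n_cells, duration=duration, frame_interval=float(p.get("frame_interval", 1.0)),
        glucose_media_schedule=[(0.0, 25.0), (washout, 0.0), (washin, 25.0)],
        noise_sd=float(p.get("noise_sd", 0.0)), seed=seed, motion_sd=0.0,
    )
    model = BiosensorModel()
    rng = np.random.default_rng(seed)
    traces, truth = [], {}
    margin = 12
    grid = int(np.ceil(np.sqrt(n_cells)))
    for i in range(n_cells):
        vup = float(rng.uniform(0.05, 0.25))
        vcon = float(rng.uniform(0.1, 0.5))
        cell = CellParams(cell_id=i + 1, vup=vup, vcon=vcon, g0=2.0)
        gx = margin + (i % grid) * (shape[1] - 2 * margin) / grid
        gy = margin + (i // grid) * (shape[0] - 2 * margin) / grid
        tr = simulate_cell_trace(scen, model, cell, rng=rng, xy0=(gx + 5, gy + 5))
        traces.append(tr)
        truth[cell.cell_id] = {"vup": vup, "vcon": vcon, "g0": 2.0}
    donor, acceptor, masks = render_movie(traces, shape, cell_radius=6.0)
    files = []
    for name, arr in [("movie_donor.tif", donor.astype(np.float32)),
                      ("movie_fret.tif", acceptor.astype(np.float32)),
                      ("masks.tif", masks)]:
        mio.write_stack(out / name, arr)
        files.append(out / name)
    mio.write_traces_csv(out / "traces.csv", traces)
    files.append(out / "traces.csv")
    mio.write_json(out / "truth.json", {
        "cells": truth, "washout_min": washout, "washin_min": washin,
        "scenario": scen.model_dump(), "seed": seed,
    })
    files.append(out / "truth.json")
    return files


def _stage_quantify(cfg: RunConfig, out: Path) -> list[Path]:
    donor = mio.read_stack(out / "movie_donor.tif")
    acceptor = mio.read_stack(out / "movie_fret.tif")
    masks = mio.read_stack(out / "masks.tif")
    truth = mio.read_json(out / "truth.json")
    interval = float(truth["scenario"]["frame_interval"])
    rows = []
    for f in range(donor.shape[0]):
        tab = measure_cell_fret(donor[f], acceptor[f], masks[f].astype(np.int32), background="mode")
        tab["frame"] = f
        tab["time_min"] = f * interval
        rows.append(tab)
    df = pd.concat(rows, ignore_index=True)
    df = df.rename(columns={})[["frame", "time_min", "cell_id", "donor_mean",
                                "acceptor_mean", "ratio", "x", "y"]]
    df["parent_id"] = -1
    df.to_csv(out / "measured_traces.csv", index=False)
    return [out / "measured_traces.csv"]


def _stage_kinetics(cfg: RunConfig, out: Path) -> list[Path]:
    truth = mio.read_json(out / "truth.json")
    washout, washin = truth["washout_min"], truth["washin_min"]
    traces = frame_to_traces(pd.read_csv(out / "measured_traces.csv"))
    rows = []
    for tr in traces:
        flux = uptake_rate(tr, washout, washin)
        fit = fit_one_phase_decay(tr.times, tr.ratio, t0=washout, t_end=washin)
        rows.append(dict(cell_id=tr.cell_id, k=fit.k, t_half=fit.t_half,
                         consumption=flux.consumption, refill=flux.refill_slope,
                         uptake=flux.uptake,
                         washout_window=str(flux.washout_window),
                         washin_window=str(flux.washin_window)))
    pd.DataFrame(rows).to_csv(out / "kinetics.csv", index=False)
    return [out / "kinetics.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "kinetics": _stage_kinetics,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("metaboscope")
    root.addHandler(handler)
    manifest: dict = {"schema_version": config.schema_version, "seed": config.seed,
                      "stages": [], "files": {}}
    try:
        for stage in config.stages:
            if stage not in _STAGE_FUNCS:
                raise ValueError(f"stage {stage!r} has no runner")
            t0 = time.perf_counter()
            log.info("stage %s: start (seed %d)", stage, config.stage_seed(stage))
            try:
                files = _STAGE_FUNCS[stage](config, out)
            except Exception:
                snap = out / f"failed_{stage}_config.json"
                snap.write_text(config.model_dump_json(indent=2))
                log.exception("stage %s failed; config snapshot at %s", stage, snap)
                raise RuntimeError(f"stage {stage!r} failed (snapshot: {snap})")
            wall = time.perf_counter() - t0
            log.info("stage %s: done in %.2fs", stage, wall)
            manifest["stages"].append({"name": stage, "wall_s": wall,
                                       "seed": config.stage_seed(stage)})
            for f in files:
                manifest["files"][f.name] = _sha256(f)
    finally:
        root.removeHandler(handler)
        handler.close()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
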