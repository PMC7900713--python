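"""Simulated single-cell glucose traces and heritable lineage cohorts.

The intracellular glucose pool G (mM) of one cell follows

    dG/dt = Vup * G_ext / (K_media + G_ext)  -  Vcon * G / (Km + G)

with a piecewise-constant media schedule G_ext(t).  Uptake saturates with
extracellular glucose and stops in glucose-free medium; consumption is
Michaelis-Menten in the intracellular pool, which produces the curved
wash-out decays seen in biosensor traces.  The emitted FRET ratio maps G
through the saturable biosensor response plus Gaussian read noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from ..config import BiosensorModel, ScenarioConfig
from ..trace import CellTrace


@dataclass
class CellParams:
    """Ground-truth kinetic parameters for one simulated cell."""

    cell_id: int
    vup: float  # mM/min at saturating media
    vcon: float  # mM/min at saturating intracellular glucose
    g0: float  # initial intracellular glucose, mM
    state: float = 0.0  # standardized glycolytic state
    state_label: str = "high"
    parent_id: Optional[int] = None


@dataclass
class GroundTruth:
    """Truth channel recorded by the generators for recovery testing."""

    params: dict[int, CellParams] = field(default_factory=dict)
    tree: nx.DiGraph = field(default_factory=nx.DiGraph)
    birth_time: dict[int, float] = field(default_factory=dict)
    death_time: dict[int, float] = field(default_factory=dict)
    responder_class: dict[int, str] = field(default_factory=dict)
    refractory: dict[int, bool] = field(default_factory=dict)

    def parent_of(self, cell_id: int) -> Optional[int]:
        preds = list(self.tree.predecessors(cell_id)) if cell_id in self.tree else []
        return preds[0] if preds else None


def _validate_cell(params: CellParams) -> None:
    if params.vup < 0 or params.vcon < 0:
        raise ValueError("uptake and consumption rates must be >= 0")
    if params.g0 < 0:
        raise ValueError("initial glucose must be >= 0")


def integrate_glucose(
    config: ScenarioConfig,
    vup: float,
    vcon: float,
    g0: float,
    substeps: int = 20,
) -> np.ndarray:
    """RK4 integration of the glucose ODE on the frame grid.

    ``substeps`` RK4 steps per frame keep the discretization error far below
    the fitting tolerances used downstream.
    """
    times = config.times
    km, kmed = config.km_consumption, config.k_media
    g = float(g0)
    out = np.empty(len(times))
    out[0] = g
    h = config.frame_interval / substeps

    # media is held constant within each substep (evaluated at the substep
    # start), so switch times aligned with the frame grid are integrated
    # exactly rather than smeared across an RK4 stage
    def rhs(g_ext: float, gv: float) -> float:
        gv = max(gv, 0.0)
        return vup * g_ext / (kmed + g_ext) - vcon * gv / (km + gv)

    for i in range(1, len(times)):
        t = times[i - 1]
        for s in range(substeps):
            g_ext = float(config.media_glucose(t + s * h)[0])
            k1 = rhs(g_ext, g)
            k2 = rhs(g_ext, g + h * k1 / 2)
            k3 = rhs(g_ext, g + h * k2 / 2)
            k4 = rhs(g_ext, g + h * k3)
            g = max(g + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6, 0.0)
        out[i] = g
    return out


def simulate_cell_trace(
    config: ScenarioConfig,
    model: BiosensorModel,
    cell: CellParams,
    rng: Optional[np.random.Generator] = None,
    xy0: Optional[tuple[float, float]] = None,
) -> CellTrace:
    """Simulate one cell's FRET-ratio trace under the media schedule."""
    _validate_cell(cell)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    glucose = integrate_glucose(config, cell.vup, cell.vcon, cell.g0)
    ratio = np.asarray(model.response(glucose), dtype=float)
    if config.noise_sd > 0:
        ratio = ratio + rng.normal(0.0, config.noise_sd, size=ratio.shape)
    xy = None
    if xy0 is not None:
        steps = rng.normal(0.0, config.motion_sd, size=(len(ratio), 2))
        steps[0] = 0.0
        xy = np.asarray(xy0, dtype=float) + np.cumsum(steps, axis=0)
    return CellTrace(cell_id=cell.cell_id, times=config.times, ratio=ratio, xy=xy,
                     parent_id=cell.parent_id)


def simulate_sorted_population(
    start_offset: float,
    relaxation_days: float,
    n_cells: int = 200,
    n_days: float = 6.0,
    samples_per_day: int = 4,
    state_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """FACS-sorted subpopulation relaxing back to the population mean.

    Per-cell states follow an Ornstein-Uhlenbeck process around 0 with
    relaxation time ``relaxation_days`` and stationary SD ``state_sd``; the
    sorted population starts displaced by ``start_offset``.  Returns
    (times_min, list of per-cell state arrays per time point), matching the
    input of :func:`metaboscope.lineage.return_to_mean`.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(n_days * samples_per_day) + 1
    dt_days = 1.0 / samples_per_day
    decay = math.exp(-dt_days / relaxation_days)
    innov_sd = state_sd * math.sqrt(1 - decay ** 2)
    x = start_offset + rng.normal(0, 0.2 * state_sd, size=n_cells)
    times_min = np.arange(n_samples) * dt_days * 24 * 60
    values = [x.copy()]
    for _ in range(n_samples - 1):
        x = x * decay + rng.normal(0, innov_sd, size=n_cells)
        values.append(x.copy())
    return times_min, values


def washout_truth(
    config: ScenarioConfig,
    model: BiosensorModel,
    cell: CellParams,
    washout_time: float,
    washin_time: float,
) -> dict[str, float]:
    """True instantaneous slopes (ratio units/min) at the medium switches.

    The truth channel for kinetic recovery: the consumption read is the rate
    of ratio decline just after wash-out; the refill read is the rate of
    ratio rise just after wash-in; true uptake is their sum (the same
    identity the estimator uses, evaluated on the noiseless model).
    """
    glucose = integrate_glucose(config, cell.vup, cell.vcon, cell.g0)
    times = config.times
    km, kmed = config.km_consumption, config.k_media

    def dratio_dg(g: float) -> float:
        h, kd = model.hill, model.kd
        g = max(g, 1e-12)
        num = (model.r_max - model.r_min) * h * kd ** h * g ** (h - 1)
        return num / (kd ** h + g ** h) ** 2

    def dgdt(t: float, g: float) -> float:
        g_ext = float(config.media_glucose(t)[0])
        return cell.vup * g_ext / (kmed + g_ext) - cell.vcon * g / (km + g)

    g_out = float(np.interp(washout_time, times, glucose))
    g_in = float(np.interp(washin_time, times, glucose))
    cons = -dratio_dg(g_out) * dgdt(washout_time + 1e-9, g_out)
    refill = dratio_dg(g_in) * dgdt(washin_time + 1e-9, g_in)
    return {
        "g_washout": g_out,
        "g_washin": g_in,
        "true_consumption": cons,
        "true_refill": refill,
        "true_uptake": cons + refill,
    }


# --- heritable lineage cohorts -------------------------------------------

#: ratio units added per unit of standardized glycolytic state
STATE_RATIO_SCALE = 0.25
STATE_RATIO_CENTER = 2.0


def _founder_states(config: ScenarioConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Standardized founder states from the high/low mixture.

    High/low labels shift the state mean by ±1 before standardization, so the
    population state is mean-0, SD-1 regardless of the mix.
    """
    labels = rng.choice(
        list(config.state_mix.keys()),
        size=config.n_cells,
        p=list(config.state_mix.values()),
    )
    mu = np.where(labels == "high", 1.0, -1.0)
    z = mu + rng.normal(0.0, 0.5, size=config.n_cells)
    p_high = config.state_mix.get("high", 0.0)
    m = p_high * 1.0 + (1 - p_high) * (-1.0)
    var = 0.25 + (p_high * (1 - m) ** 2 + (1 - p_high) * (-1 - m) ** 2)
    return (z - m) / math.sqrt(var), [str(l) for l in labels]


def simulate_lineage_cohort(
    config: ScenarioConfig,
    model: Optional[BiosensorModel] = None,
    image_shape: Optional[tuple[int, int]] = None,
    margin: float = 12.0,
) -> tuple[list[CellTrace], GroundTruth]:
    """Branching cohort with AR(1) inheritance of the glycolytic state.

    Each track ends at division and two child tracks begin; a daughter's
    standardized state is ``rho * parent + sqrt(1 - rho^2) * innovation``.
    The baseline FRET ratio is an affine map of the state; per-frame read
    noise is added on top.  The lineage tree, per-cell states and birth/death
    times are recorded in the returned :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.heritability_rho
    rate_per_min = config.division_rate / 60.0
    times = config.times
    dt = config.frame_interval

    states, labels = _founder_states(config, rng)
    truth = GroundTruth()
    traces: list[CellTrace] = []
    next_id = 1
    # (cell_id, birth_time, state, label, parent, xy)
    stack: list[tuple[int, float, float, str, Optional[int], Optional[np.ndarray]]] = []
    for i in range(config.n_cells):
        xy = None
        if image_shape is not None:
            xy = rng.uniform([margin, margin],
                             [image_shape[1] - margin, image_shape[0] - margin])
        stack.append((next_id, 0.0, float(states[i]), labels[i], None, xy))
        next_id += 1

    while stack:
        cid, birth, state, label, parent, xy0 = stack.pop(0)
        if rate_per_min > 0:
            life = rng.exponential(1.0 / rate_per_min)
        else:
            life = math.inf
        death = birth + life
        # snap death to the frame grid; track must span >= 2 frames
        end = min(death, config.duration)
        t_mask = (times >= birth - 1e-9) & (times <= end + 1e-9)
        t_cell = times[t_mask]
        if len(t_cell) < 2:
            t_idx = np.searchsorted(times, birth)
            t_cell = times[t_idx:min(t_idx + 2, len(times))]
            if len(t_cell) < 2:
                continue
        baseline = STATE_RATIO_CENTER + STATE_RATIO_SCALE * state
        ratio = baseline + rng.normal(0.0, config.noise_sd, size=len(t_cell))
        xy = None
        if xy0 is not None:
            steps = rng.normal(0.0, config.motion_sd, size=(len(t_cell), 2))
            steps[0] = 0.0
            xy = np.asarray(xy0, float) + np.cumsum(steps, axis=0)
        traces.append(CellTrace(cell_id=cid, times=t_cell, ratio=ratio, xy=xy, parent_id=parent))
        truth.params[cid] = CellParams(cell_id=cid, vup=0.0, vcon=0.0, g0=0.0,
                                       state=state, state_label=label, parent_id=parent)
        truth.tree.add_node(cid)
        if parent is not None:
            truth.tree.add_edge(parent, cid)
        truth.birth_time[cid] = float(t_cell[0])
        truth.death_time[cid] = float(t_cell[-1])
        if death < config.duration - dt:  # divides within the movie
            div_t = float(t_cell[-1])
            for _ in range(2):
                child_state = rho * state + math.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal()
                child_xy = None if xy is None else xy[-1] + rng.normal(0, 2.0, size=2)
                stack.append((next_id, div_t + dt, child_state, label, cid, child_xy))
                next_id += 1
    return traces, truth
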