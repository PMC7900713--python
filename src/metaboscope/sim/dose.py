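"""Stepped-inhibitor cohorts with responder classes and refractory cells.

Responder phenotypes (fractional FRET-ratio shifts reached by the end of
each dose dwell, relative to the pre-drug baseline):

* ``strong`` — large drop already at the lowest nonzero dose;
* ``weak`` — small initial drop, substantial drop by the final dose;
* ``non`` — essentially flat at every dose.

Drug-refractory cells are constitutively high-glucose and unresponsive: their
ratio stays above the control population's median at every dose.  To keep the
median rule informative, non-refractory non-responders are generated with a
low baseline glucose state — cells with little inhibitor-sensitive uptake to
lose, which also keeps their unresponsive traces below the control median.
Responses approach each step's target shift exponentially (τ = 10 min).
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from ..config import DoseSchedule
from ..trace import CellTrace
from .traces import CellParams, GroundTruth

#: (baseline mean, baseline SD, per-step target shifts, response-scale SD);
#: each cell scales its class's shift profile by one positive factor, so
#: per-dose responses are monotone per cell by construction
CLASS_PARAMS = {
    "strong": (2.10, 0.10, (-0.35, -0.45, -0.55), 0.12),
    "weak": (2.00, 0.10, (-0.08, -0.17, -0.25), 0.12),
    "non": (1.80, 0.06, (-0.005, -0.012, -0.02), 0.12),
}
REFRACTORY_BASELINE = (2.40, 0.07)
CONTROL_BASELINE = (2.00, 0.15)
RESPONSE_TAU_MIN = 10.0


def _trace_from_shifts(
    times_min: np.ndarray,
    step_times_min: np.ndarray,
    baseline: float,
    target_shifts: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise exponential approach of the ratio to each step's target."""
    ratio = np.full_like(times_min, baseline, dtype=float)
    level = 0.0  # current fractional shift
    for i, t0 in enumerate(step_times_min):
        t1 = step_times_min[i + 1] if i + 1 < len(step_times_min) else np.inf
        m = (times_min >= t0) & (times_min < t1)
        target = target_shifts[i]
        shift = target + (level - target) * np.exp(-(times_min[m] - t0) / RESPONSE_TAU_MIN)
        ratio[m] = baseline * (1.0 + shift)
        if m.any():
            level = shift[-1] if len(shift) else level
    if noise_sd > 0:
        ratio = ratio + rng.normal(0, noise_sd, size=ratio.shape)
    return ratio


def simulate_dose_cohort(
    schedule: DoseSchedule,
    mix: tuple[float, float, float] = (0.3, 0.4, 0.3),
    refractory_fraction: float = 0.1,
    n_cells: int = 600,
    n_control: int = 300,
    frame_interval_min: float = 5.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[CellTrace], list[CellTrace], GroundTruth]:
    """Treated + untreated control cohorts under a stepped dose schedule.

    ``mix`` gives the (non, weak, strong) class fractions among non-refractory
    cells; ``refractory_fraction`` of all treated cells are refractory (truth
    class "non").  Returns (treated, control, truth).
    """
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    if not (0.0 <= refractory_fraction <= 1.0):
        raise ValueError("refractory_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, schedule.end_time * 60.0 + 1e-9, frame_interval_min)
    step_times = np.array([t for t, _ in schedule.steps]) * 60.0
    truth = GroundTruth()
    treated: list[CellTrace] = []
    refractory = rng.random(n_cells) < refractory_fraction
    classes = rng.choice(["non", "weak", "strong"], size=n_cells, p=list(mix))
    classes[refractory] = "non"
    for i in range(n_cells):
        cid = i + 1
        if refractory[i]:
            b_mu, b_sd = REFRACTORY_BASELINE
            baseline = rng.normal(b_mu, b_sd)
            shifts = np.zeros(len(step_times))
        else:
            b_mu, b_sd, sh_mu, scale_sd = CLASS_PARAMS[classes[i]]
            baseline = rng.normal(b_mu, b_sd)
            resp_scale = max(rng.normal(1.0, scale_sd), 0.1)
            shifts = np.concatenate([[0.0], resp_scale * np.array(sh_mu)])
        ratio = _trace_from_shifts(times, step_times, baseline, shifts, noise_sd, rng)
        treated.append(CellTrace(cell_id=cid, times=times, ratio=ratio))
        truth.params[cid] = CellParams(cell_id=cid, vup=0.0, vcon=0.0, g0=0.0)
        truth.responder_class[cid] = str(classes[i])
        truth.refractory[cid] = bool(refractory[i])
    control: list[CellTrace] = []
    c_mu, c_sd = CONTROL_BASELINE
    for j in range(n_control):
        baseline = rng.normal(c_mu, c_sd)
        ratio = baseline + rng.normal(0, noise_sd, size=len(times))
        control.append(CellTrace(cell_id=10_000 + j, times=times, ratio=ratio))
    return treated, control, truth
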