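"""Single-cell classification of stepped inhibitor responses.

Each cell's FRET ratio is sampled at per-step assay times; the fractional
shift from the pre-drug baseline drives a three-way non/weak/strong call,
and cells whose ratio stays above the untreated control population's median
at the maximal dose are flagged drug-refractory.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import DoseSchedule
from .trace import CellTrace

log = logging.getLogger(__name__)

#: default class thresholds on the fractional (baseline-normalized) shift
T_STRONG = 0.2  # strong: shift at lowest nonzero dose <= -T_STRONG
T_NON = 0.05  # non: final shift >= -T_NON


def per_step_response(
    trace: CellTrace,
    schedule: DoseSchedule,
    halfwidth_min: float = 5.0,
    normalized: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (ratio, shift) sampled at the schedule's assay times.

    The ratio at each assay time is the mean of frames within ±5 min.
    ``shift_i = (ratio_i - ratio_0) / ratio_0`` (set ``normalized=False`` for
    absolute shifts).  A cell missing frames at any assay time raises.
    """
    assay_min = np.asarray(schedule.resolved_assay_times()) * 60.0
    ratios = np.empty(len(assay_min))
    for i, ta in enumerate(assay_min):
        m = np.abs(trace.times - ta) <= halfwidth_min + 1e-9
        if not m.any():
            raise ValueError(f"cell {trace.cell_id}: no frames within ±{halfwidth_min} min of {ta} min")
        ratios[i] = trace.ratio[m].mean()
    shifts = (ratios - ratios[0]) / (ratios[0] if normalized else 1.0)
    return ratios, shifts


def classify_responder(shifts: np.ndarray, t_strong: float = T_STRONG, t_non: float = T_NON) -> str:
    """non/weak/strong call from the per-step fractional shifts.

    strong — shift at the lowest nonzero dose (step 1) <= -t_strong;
    non — final shift >= -t_non; weak — everything between.
    """
    if t_strong <= t_non:
        raise ValueError("thresholds must satisfy t_strong > t_non")
    shifts = np.asarray(shifts, dtype=float)
    if len(shifts) >= 2 and shifts[1] <= -t_strong:
        return "strong"
    if shifts[-1] >= -t_non:
        return "non"
    return "weak"


@dataclass
class RefractoryResult:
    flags: np.ndarray  # boolean per treated cell
    fraction: float
    ci_low: float
    ci_high: float
    control_median: float
    n_treated: int
    n_control: int


def flag_refractory(
    treated_final_ratios: np.ndarray,
    control_ratios: np.ndarray,
    min_control: int = 20,
) -> RefractoryResult:
    """Refractory = final ratio strictly above the control population median."""
    treated = np.asarray(treated_final_ratios, dtype=float)
    control = np.asarray(control_ratios, dtype=float)
    if len(control) < min_control:
        raise ValueError(f"need a control population of n >= {min_control}")
    med = float(np.median(control))
    flags = treated > med
    k, n = int(flags.sum()), len(flags)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return RefractoryResult(flags=flags, fraction=k / n, ci_low=float(lo), ci_high=float(hi),
                            control_median=med, n_treated=n, n_control=len(control))


def analyze_dose_cohort(
    treated: list[CellTrace],
    control: list[CellTrace],
    schedule: DoseSchedule,
    t_strong: float = T_STRONG,
    t_non: float = T_NON,
    halfwidth_min: float = 5.0,
) -> pd.DataFrame:
    """ResponderCall table for a treated cohort against its control.

    Columns: cell_id, class, refractory, ratio_step*/shift_step* per step.
    Cells missing assay frames are excluded and logged.
    """
    rows, final_ratios, ids = [], [], []
    n_steps = len(schedule.steps)
    for tr in treated:
        try:
            ratios, shifts = per_step_response(tr, schedule, halfwidth_min)
        except ValueError as err:
            log.warning("%s; excluded", err)
            continue
        row = {"cell_id": tr.cell_id, "class": classify_responder(shifts, t_strong, t_non)}
        for i in range(n_steps):
            row[f"ratio_step{i}"] = ratios[i]
            row[f"shift_step{i}"] = shifts[i]
        rows.append(row)
        final_ratios.append(ratios[-1])
        ids.append(tr.cell_id)
    df = pd.DataFrame(rows)
    assay_final = schedule.resolved_assay_times()[-1] * 60.0
    control_final = []
    for tr in control:
        m = np.abs(tr.times - assay_final) <= halfwidth_min + 1e-9
        if m.any():
            control_final.append(tr.ratio[m].mean())
    res = flag_refractory(np.asarray(final_ratios), np.asarray(control_final))
    df["refractory"] = res.flags
    df.attrs["refractory_fraction"] = res.fraction
    df.attrs["refractory_ci"] = (res.ci_low, res.ci_high)
    df.attrs["control_median"] = res.control_median
    return df
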