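"""Kinetic decomposition of glucose handling from wash-out/wash-in traces.

A medium switch to 0 mM glucose halts uptake, so the biosensor signal decays
at the cell's consumption rate; switching back to high glucose restores
uptake, and the signal's refill slope reports uptake net of the ongoing
consumption.  Uptake is therefore recovered as the definitional sum

    uptake = consumption + refill_slope .

The wash-out decay is summarized by a one-phase exponential fit
``y(t) = plateau + span * exp(-k (t - t0))`` with half-life t1/2 = ln2 / k;
initial slopes use ordinary least squares over a short configurable window
(default 3 min, immediately after the medium switch).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .trace import CellTrace

#: default slope window, minutes (the consumption read spans the 3 minutes
#: immediately after the 10-min wash-out, i.e. minutes 10-13 of the protocol)
DEFAULT_WINDOW_MIN = 3.0


@dataclass
class DecayFit:
    k: float  # 1/min
    plateau: float
    span: float
    t_half: float  # = ln2 / k, minutes
    rss: float
    window: tuple[float, float]
    converged: bool = True
    message: str = ""


@dataclass
class FluxEstimate:
    consumption: float  # ratio units / min
    refill_slope: float
    uptake: float  # = consumption + refill_slope, exact identity
    washout_window: tuple[float, float]
    washin_window: tuple[float, float]


def _one_phase(t, plateau, span, k):
    return plateau + span * np.exp(-k * t)


def fit_one_phase_decay(
    times: np.ndarray,
    values: np.ndarray,
    t0: Optional[float] = None,
    t_end: Optional[float] = None,
    param_tol: float = 1e-8,
) -> DecayFit:
    """Least-squares one-phase decay fit on the segment t0 <= t <= t_end.

    Initial guesses come from the endpoints (plateau, span) and the
    log-linear slope of the baseline-subtracted early samples (k).
    Non-convergence returns a flagged fit rather than raising.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    t0 = times[0] if t0 is None else t0
    t_end = times[-1] if t_end is None else t_end
    m = (times >= t0 - 1e-12) & (times <= t_end + 1e-12)
    t, y = times[m] - t0, values[m]
    if len(t) < 5:
        raise ValueError("need at least 5 samples after t0")
    if np.allclose(y, y[0]):
        raise ValueError("constant input: no decay to fit")
    plateau0 = float(y[-1])
    span0 = float(y[0] - plateau0)
    # log-linear slope estimate for k on the positive part of y - plateau0
    resid = (y - plateau0) * np.sign(span0 if span0 != 0 else 1.0)
    good = resid > 1e-12
    if good.sum() >= 2:
        slope = np.polyfit(t[good], np.log(resid[good]), 1)[0]
        k0 = max(-slope, 1e-3)
    else:
        k0 = 1.0 / max(t[-1] / 3.0, 1e-6)
    try:
        popt, _ = curve_fit(
            _one_phase, t, y, p0=[plateau0, span0, k0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            xtol=param_tol, ftol=param_tol * 1e-2, maxfev=20000,
        )
        plateau, span, k = (float(v) for v in popt)
        rss = float(np.sum((_one_phase(t, *popt) - y) ** 2))
        return DecayFit(k=k, plateau=plateau, span=span, t_half=math.log(2) / k,
                        rss=rss, window=(t0, t0 + t[-1]))
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        return DecayFit(k=np.nan, plateau=np.nan, span=np.nan, t_half=np.nan,
                        rss=np.nan, window=(t0, t0 + t[-1]),
                        converged=False, message=str(err))


def _window_slope(times: np.ndarray, values: np.ndarray, start: float, length: float,
                  mode: str = "ols") -> float:
    m = (times >= start - 1e-9) & (times <= start + length + 1e-9)
    t, y = times[m], values[m]
    if len(t) < 3:
        raise ValueError(f"fewer than 3 samples in window [{start}, {start + length}] min")
    if mode == "ols":
        return float(np.polyfit(t, y, 1)[0])
    if mode == "diff":  # two-point difference, for exact replication studies
        return float((y[-1] - y[0]) / (t[-1] - t[0]))
    raise ValueError("mode must be 'ols' or 'diff'")


def consumption_rate(
    trace: CellTrace,
    washout_time: float,
    window: float = DEFAULT_WINDOW_MIN,
    mode: str = "ols",
) -> float:
    """Consumption = negative initial slope of the post-wash-out drop (ratio/min)."""
    return -_window_slope(trace.times, trace.ratio, washout_time, window, mode)


def uptake_rate(
    trace: CellTrace,
    washout_time: float,
    washin_time: float,
    window: float = DEFAULT_WINDOW_MIN,
    mode: str = "ols",
) -> FluxEstimate:
    """Kinetic decomposition: uptake = consumption + post-wash-in refill slope."""
    if washin_time <= washout_time + window:
        raise ValueError("wash-in window must follow the wash-out window")
    consumption = consumption_rate(trace, washout_time, window, mode)
    refill = _window_slope(trace.times, trace.ratio, washin_time, window, mode)
    return FluxEstimate(
        consumption=consumption,
        refill_slope=refill,
        uptake=consumption + refill,
        washout_window=(washout_time, washout_time + window),
        washin_window=(washin_time, washin_time + window),
    )


@dataclass
class StabilityStats:
    cell_id: int
    mean: float
    variance: float
    ratio_start: float
    ratio_end: float
    flagged: bool = False


def trace_stability(trace: CellTrace, window_h: float = 10.0, max_gap_fraction: float = 0.2) -> StabilityStats:
    """Per-cell mean/variance over a 10-h window and the (0 h, 10 h) endpoints."""
    t0 = trace.times[0]
    span_min = window_h * 60.0
    if trace.times[-1] - t0 < span_min - 1e-9:
        raise ValueError(f"trace must span at least {window_h} h")
    m = trace.times <= t0 + span_min + 1e-9
    t, y = trace.times[m], trace.ratio[m]
    interval = np.median(np.diff(t))
    expected = int(round(span_min / interval)) + 1
    flagged = len(t) < (1 - max_gap_fraction) * expected
    return StabilityStats(
        cell_id=trace.cell_id,
        mean=float(y.mean()),
        variance=float(y.var(ddof=0)),
        ratio_start=float(y[0]),
        ratio_end=float(y[np.argmin(np.abs(t - (t0 + span_min)))]),
        flagged=flagged,
    )


def endpoint_correlation(stats: list[StabilityStats]) -> tuple[float, int]:
    """Population Pearson r of the (0 h, 10 h) endpoint pairs."""
    a = np.array([s.ratio_start for s in stats])
    b = np.array([s.ratio_end for s in stats])
    if len(a) < 3:
        raise ValueError("need >= 3 cells")
    return float(pearsonr(a, b).statistic), len(a)
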