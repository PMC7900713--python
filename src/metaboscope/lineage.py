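"""Mitosis-synchronized trace analysis and cross-generation heritability.

Founder traces are relabeled so their first division sits at T = 0, with one
track giving rise to two daughter tracks on the same axis.  Heritability is
read out as the Pearson correlation of per-cell summary ratios between
ancestors and descendants; an AR(1) state process predicts parent-daughter
correlation rho and grandparent-granddaughter correlation rho^2, i.e. a
decline across generations.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .trace import CellTrace

log = logging.getLogger(__name__)

#: per-cell summary for correlations: mean ratio over this window before division
SUMMARY_WINDOW_MIN = 120.0


def build_lineage_table(traces: list[CellTrace]) -> pd.DataFrame:
    """LineageTable: id, parent, generation (founder = 1), birth/death, summary.

    The summary ratio is the mean over the last 2 h of the track (or the whole
    track if shorter) — the state carried into division.
    """
    by_id = {t.cell_id: t for t in traces}
    gen: dict[int, int] = {}

    def generation(cid: int) -> int:
        if cid in gen:
            return gen[cid]
        tr = by_id[cid]
        g = 1 if tr.parent_id is None or tr.parent_id not in by_id else generation(tr.parent_id) + 1
        gen[cid] = g
        return g

    rows = []
    for tr in traces:
        m = tr.times >= tr.times[-1] - SUMMARY_WINDOW_MIN
        rows.append(dict(
            cell_id=tr.cell_id,
            parent_id=-1 if tr.parent_id is None else tr.parent_id,
            generation=generation(tr.cell_id),
            birth_min=float(tr.times[0]),
            death_min=float(tr.times[-1]),
            summary_ratio=float(tr.ratio[m].mean()),
        ))
    df = pd.DataFrame(rows)
    g = nx.DiGraph()
    g.add_nodes_from(df["cell_id"])
    g.add_edges_from(df.loc[df["parent_id"] > 0, ["parent_id", "cell_id"]].itertuples(index=False))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("lineage contains a cycle")
    return df


def synchronize_to_mitosis(traces: list[CellTrace]) -> list[CellTrace]:
    """Shift each founder family so the founder's first division is T = 0.

    Daughter tracks continue on the same axis.  Founders that never divide
    are excluded (logged); if no family divides, an empty list is returned
    with a warning.  Every retained sample keeps its value — relabeling only.
    """
    by_id = {t.cell_id: t for t in traces}
    children: dict[int, list[CellTrace]] = {}
    for t in traces:
        if t.parent_id is not None:
            children.setdefault(t.parent_id, []).append(t)

    def founder_of(tr: CellTrace) -> CellTrace:
        cur = tr
        while cur.parent_id is not None and cur.parent_id in by_id:
            cur = by_id[cur.parent_id]
        return cur

    out: list[CellTrace] = []
    offsets: dict[int, float] = {}
    for tr in traces:
        if tr.parent_id is None or tr.parent_id not in by_id:
            if tr.cell_id in children:
                offsets[tr.cell_id] = -float(tr.times[-1])  # division = end of founder track
            else:
                log.info("founder %d never divides; excluded from synchronization", tr.cell_id)
    if not offsets:
        warnings.warn("no divisions found; synchronized output is empty", stacklevel=2)
        return []
    for tr in traces:
        f = founder_of(tr)
        if f.cell_id in offsets:
            out.append(tr.shifted(offsets[f.cell_id]))
    return out


@dataclass
class GenerationCorrelation:
    r_parent_daughter: float
    n_parent_daughter: int
    r_grandparent_granddaughter: float
    n_grandparent_granddaughter: int
    low_n: bool = False


def generation_correlation(
    lineage: pd.DataFrame,
    one_per_family: bool = False,
    rng: Optional[np.random.Generator] = None,
    min_pairs: int = 10,
) -> GenerationCorrelation:
    """Pearson r of summary ratios across one and two generations.

    Every daughter contributes one (parent, daughter) pair by default (all
    progeny are plotted); ``one_per_family`` subsamples a single daughter per
    parent for independent-pair statistics.
    """
    summ = lineage.set_index("cell_id")["summary_ratio"]
    parent = lineage.set_index("cell_id")["parent_id"]
    df = lineage[lineage["parent_id"] > 0].copy()
    if one_per_family:
        rng = np.random.default_rng() if rng is None else rng
        df = df.groupby("parent_id", group_keys=False).apply(
            lambda g: g.iloc[rng.integers(len(g))], include_groups=False
        ).reset_index()

    def pairs(df_desc: pd.DataFrame, hops: int) -> tuple[np.ndarray, np.ndarray]:
        anc_vals, desc_vals = [], []
        for cid, pid in zip(df_desc["cell_id"], df_desc["parent_id"]):
            anc = pid
            ok = True
            for _ in range(hops - 1):
                anc = parent.get(anc, -1)
                if anc <= 0:
                    ok = False
                    break
            if ok and anc in summ.index:
                anc_vals.append(summ[anc])
                desc_vals.append(summ[cid])
        return np.array(anc_vals), np.array(desc_vals)

    a1, d1 = pairs(df, 1)
    a2, d2 = pairs(df, 2)

    def corr(a, d):
        if len(a) < 2 or np.std(a) == 0 or np.std(d) == 0:
            return np.nan, len(a)
        return float(pearsonr(a, d).statistic), len(a)

    r1, n1 = corr(a1, d1)
    r2, n2 = corr(a2, d2)
    return GenerationCorrelation(r1, n1, r2, n2, low_n=(n1 < min_pairs or n2 < min_pairs))


def binned_cohort_traces(
    synchronized: list[CellTrace],
    n_bins: int = 4,
    grid_interval: Optional[float] = None,
) -> pd.DataFrame:
    """Per-bin mean/variance traces, binned by founder ratio at T = 0.

    Cells are binned by their family founder's ratio at the first mitosis
    (T = 0); all progeny inherit the founder's bin.  Returns a tidy frame
    (bin, time_min, mean, variance, n); empty bins are simply absent.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    by_id = {t.cell_id: t for t in synchronized}

    def founder_of(tr: CellTrace) -> CellTrace:
        cur = tr
        while cur.parent_id is not None and cur.parent_id in by_id:
            cur = by_id[cur.parent_id]
        return cur

    founders = {t.cell_id: t for t in synchronized if t.parent_id is None or t.parent_id not in by_id}
    r0 = {cid: t.ratio[np.argmin(np.abs(t.times - 0.0))] for cid, t in founders.items()}
    vals = np.array(list(r0.values()))
    if np.all(vals == vals[0]):
        edges = np.array([vals[0] - 0.5, vals[0] + 0.5])
        bin_of = {cid: 0 for cid in r0}
    else:
        edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
        bin_of = {cid: int(np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1))
                  for cid, v in r0.items()}
    rows = []
    for tr in synchronized:
        b = bin_of[founder_of(tr).cell_id]
        for t, r in zip(tr.times, tr.ratio):
            rows.append((b, t, r))
    df = pd.DataFrame(rows, columns=["bin", "time_min", "ratio"])
    if grid_interval is not None:
        df["time_min"] = np.round(df["time_min"] / grid_interval) * grid_interval
    out = (
        df.groupby(["bin", "time_min"])["ratio"]
        .agg(mean="mean", variance="var", n="count")
        .reset_index()
    )
    out["variance"] = out["variance"].fillna(0.0)
    return out


@dataclass
class ReturnToMean:
    daily_median_distance: pd.DataFrame  # (day, distance)
    rate_per_day: float
    half_life_days: float
    reliable: bool


def return_to_mean(
    times_min: np.ndarray,
    population_values: list[np.ndarray],
    reference: float,
) -> ReturnToMean:
    """Convergence of a sorted subpopulation's median back to the reference.

    ``population_values[i]`` are the per-cell ratios at ``times_min[i]``.
    The per-day median distance from the reference is fitted with a decaying
    exponential; a trajectory whose |distance| re-expands beyond 1.5x a
    previous day's value is flagged unreliable.
    """
    times_min = np.asarray(times_min, dtype=float)
    if len(times_min) < 2:
        raise ValueError("need at least 2 time points")
    days = times_min / (24 * 60.0)
    dist = np.array([np.median(v) - reference for v in population_values])
    tab = pd.DataFrame({"day": days, "distance": dist})
    sign = np.sign(dist[0]) if dist[0] != 0 else 1.0
    d = sign * dist  # positive, decaying toward 0
    reliable = True
    running_min = np.minimum.accumulate(np.abs(d) + 1e-12)
    if np.any(np.abs(d)[1:] > 1.5 * running_min[:-1] + 0.05 * abs(d[0])):
        reliable = False
    if abs(d[0]) < 1e-12:
        return ReturnToMean(tab, np.inf, 0.0, True)
    try:
        popt, _ = curve_fit(lambda t, a, k: a * np.exp(-k * t), days, d,
                            p0=[d[0], 0.5], maxfev=10000)
        k = float(abs(popt[1]))
    except RuntimeError:
        k, reliable = np.nan, False
    return ReturnToMean(tab, k, np.log(2) / k if k and np.isfinite(k) else np.nan, reliable)
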