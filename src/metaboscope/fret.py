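"""Per-cell ratiometric FRET quantification from two-channel stacks.

The data-path convention throughout is a single global ratio orientation:
acceptor (sensitized emission) divided by donor, increasing with glucose.
Per-cell intensities are ratio-of-means: mean pixel intensity per channel
over the cell mask, background-subtracted, then divided.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.stats import ks_2samp
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

log = logging.getLogger(__name__)


def segment_cells(image: np.ndarray, min_area: int = 20) -> np.ndarray:
    """Threshold-and-label segmentation of one channel frame.

    Foreground is everything above the Otsu threshold; connected components
    smaller than ``min_area`` px are dropped; surviving components are
    relabeled 1..K in raster order (first-pixel scan order) so labeling is
    deterministic.  A blank frame yields an empty mask.
    """
    img = np.asarray(image, dtype=float)
    if img.min() < 0:
        raise ValueError("image must be non-negative")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)
    fg = img > threshold_otsu(img)
    lab = cc_label(fg, connectivity=2)
    if lab.max() == 0:
        return lab.astype(np.int32)
    areas = np.bincount(lab.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    out = np.zeros_like(lab, dtype=np.int32)
    # raster order of first occurrence
    flat = lab.ravel()
    first = {}
    for pos in np.flatnonzero(np.isin(flat, keep)):
        l = flat[pos]
        if l not in first:
            first[l] = pos
            if len(first) == len(keep):
                break
    for new_id, (old, _) in enumerate(sorted(first.items(), key=lambda kv: kv[1]), start=1):
        out[lab == old] = new_id
    return out


def _background(channel: np.ndarray, mask: np.ndarray, method) -> float:
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "none":
        return 0.0
    if method == "mode":
        off = channel[mask == 0]
        if off.size == 0:
            return 0.0
        # mode of off-mask intensities, on integer-rounded values
        vals, counts = np.unique(np.rint(off).astype(np.int64), return_counts=True)
        return float(vals[np.argmax(counts)])
    if method == "median":
        off = channel[mask == 0]
        return float(np.median(off)) if off.size else 0.0
    raise ValueError(f"unknown background method {method!r}")


def measure_cell_fret(
    donor: np.ndarray,
    acceptor: np.ndarray,
    mask: np.ndarray,
    background: str | float = "mode",
) -> pd.DataFrame:
    """Background-subtracted per-cell channel means and FRET ratio.

    Returns a table (cell_id, donor_mean, acceptor_mean, ratio, x, y, valid).
    A cell whose background-subtracted donor mean is <= 0 gets ratio NaN and
    ``valid=False`` — flagged rather than silently dropped.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape or donor.shape != mask.shape:
        raise ValueError("donor, acceptor and mask shapes must match")
    if not np.issubdtype(np.asarray(mask).dtype, np.integer):
        raise ValueError("mask must be an integer label image")
    ids = np.unique(mask)
    ids = ids[ids > 0]
    bg_d = _background(donor, mask, background)
    bg_a = _background(acceptor, mask, background)
    rows = []
    for cid in ids:
        m = mask == cid
        dm = float(donor[m].mean()) - bg_d
        am = float(acceptor[m].mean()) - bg_a
        ys, xs = np.nonzero(m)
        valid = dm > 0
        if not valid:
            log.warning("cell %d: donor mean <= 0 after background; ratio undefined", cid)
        rows.append(
            dict(cell_id=int(cid), donor_mean=dm, acceptor_mean=am,
                 ratio=am / dm if valid else np.nan,
                 x=float(xs.mean()), y=float(ys.mean()), valid=valid)
        )
    return pd.DataFrame(rows, columns=["cell_id", "donor_mean", "acceptor_mean",
                                       "ratio", "x", "y", "valid"])


def match_labels_iou(truth_mask: np.ndarray, pred_mask: np.ndarray, min_iou: float = 0.5) -> dict[int, int]:
    """1:1 greedy IoU matching of truth labels to predicted labels."""
    pairs = []
    for t in np.unique(truth_mask):
        if t == 0:
            continue
        tm = truth_mask == t
        for p in np.unique(pred_mask[tm]):
            if p == 0:
                continue
            pm = pred_mask == p
            iou = np.logical_and(tm, pm).sum() / np.logical_or(tm, pm).sum()
            if iou >= min_iou:
                pairs.append((iou, int(t), int(p)))
    pairs.sort(reverse=True)
    used_t, used_p, out = set(), set(), {}
    for iou, t, p in pairs:
        if t not in used_t and p not in used_p:
            out[t] = p
            used_t.add(t)
            used_p.add(p)
    return out


# --- tracking -------------------------------------------------------------


@dataclass
class Track:
    track_id: int
    frames: list[int]
    centroids: list[tuple[float, float]]  # (x, y)
    labels: list[int]  # mask label per frame
    parent_id: Optional[int] = None


def track_cells(masks: np.ndarray, max_distance: float = 15.0) -> list[Track]:
    """Nearest-centroid linking of per-frame label masks into tracks.

    Frame-to-frame assignment minimizes total centroid displacement
    (Hungarian) with links capped at ``max_distance`` px.  When a track ends
    and two unassigned components appear within the cap of its last
    centroid, the event is recorded as a division (one-to-two assignment)
    and both children carry ``parent_id``.  Components that cannot be linked
    start new tracks; ambiguous links beyond the cap terminate the track
    (logged).
    """
    n_frames = masks.shape[0]
    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 1

    def props(frame):
        return [(r.label, (r.centroid[1], r.centroid[0])) for r in regionprops(frame)]

    prev = props(masks[0])
    for lab, c in prev:
        tracks.append(Track(next_id, [0], [c], [lab]))
        active.append(tracks[-1])
        next_id += 1
    for f in range(1, n_frames):
        cur = props(masks[f])
        if not active:
            matched_cur = set()
        else:
            cost = np.full((len(active), len(cur)), 1e6)
            for i, tr in enumerate(active):
                cx, cy = tr.centroids[-1]
                for j, (_, (x, y)) in enumerate(cur):
                    d = np.hypot(x - cx, y - cy)
                    if d <= max_distance:
                        cost[i, j] = d
            ri, ci = linear_sum_assignment(cost)
            matched_cur = set()
            matched_tr = set()
            for i, j in zip(ri, ci):
                if cost[i, j] < 1e6:
                    tr = active[i]
                    tr.frames.append(f)
                    tr.centroids.append(cur[j][1])
                    tr.labels.append(cur[j][0])
                    matched_cur.add(j)
                    matched_tr.add(i)
            ended = [tr for i, tr in enumerate(active) if i not in matched_tr]
            new_active = [tr for i, tr in enumerate(active) if i in matched_tr]
            unmatched = [j for j in range(len(cur)) if j not in matched_cur]

            def dist(tr: Track, j: int, prev_point: bool = True) -> float:
                cx, cy = tr.centroids[-2] if prev_point and len(tr.centroids) > 1 else tr.centroids[-1]
                return float(np.hypot(cur[j][1][0] - cx, cur[j][1][1] - cy))

            # division, case 1: a linked track has a second new component close
            # to its previous centroid -> undo the link, end the parent, start
            # two children (one-to-two assignment)
            for j in list(unmatched):
                cands = [tr for tr in new_active
                         if tr.frames[-1] == f and dist(tr, j) <= max_distance]
                if not cands:
                    continue
                parent = min(cands, key=lambda tr: dist(tr, j))
                sib = (parent.frames.pop(), parent.centroids.pop(), parent.labels.pop())
                new_active.remove(parent)
                for lab_c in ((sib[2], sib[1]), cur[j]):
                    child = Track(next_id, [f], [lab_c[1]], [lab_c[0]], parent_id=parent.track_id)
                    next_id += 1
                    tracks.append(child)
                    new_active.append(child)
                unmatched.remove(j)
                matched_cur.add(j)
            # division, case 2: an ended track adopts two nearby unmatched components
            for tr in ended:
                cx, cy = tr.centroids[-1]
                near = sorted(
                    (j for j in unmatched
                     if np.hypot(cur[j][1][0] - cx, cur[j][1][1] - cy) <= 2 * max_distance),
                    key=lambda j: np.hypot(cur[j][1][0] - cx, cur[j][1][1] - cy),
                )[:2]
                if len(near) == 2:
                    for j in near:
                        child = Track(next_id, [f], [cur[j][1]], [cur[j][0]], parent_id=tr.track_id)
                        next_id += 1
                        tracks.append(child)
                        new_active.append(child)
                        unmatched.remove(j)
                        matched_cur.add(j)
                else:
                    log.info("track %d terminated at frame %d", tr.track_id, f)
            active = new_active
        for j, (lab, c) in enumerate(cur):
            if j not in matched_cur:
                t = Track(next_id, [f], [c], [lab])
                next_id += 1
                tracks.append(t)
                active.append(t)
    return tracks


# --- population state classification --------------------------------------


def classify_state(ratios: np.ndarray, cell_ids: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Quartile-based high/low state calls from one time point's ratios.

    Cells in the top quartile are "high", bottom quartile "low", the middle
    half "mid".  Ties are broken by stable cell_id order.  Requires >= 8
    cells; an all-identical population yields only "mid" (with a warning).
    """
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios)
    if n < 8:
        raise ValueError("need at least 8 cells for quartile classification")
    if cell_ids is None:
        cell_ids = np.arange(1, n + 1)
    cell_ids = np.asarray(cell_ids)
    if np.all(ratios == ratios[0]):
        warnings.warn("all ratios identical; no high/low calls", stacklevel=2)
        return pd.DataFrame({"cell_id": cell_ids, "quartile": 0, "label": "mid"})
    order = np.lexsort((cell_ids, ratios))  # stable: ratio, then cell_id
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    quart = np.minimum(rank * 4 // n + 1, 4)
    label = np.where(quart == 4, "high", np.where(quart == 1, "low", "mid"))
    return pd.DataFrame({"cell_id": cell_ids, "quartile": quart, "label": label})


def compare_distributions(ratios_a: np.ndarray, ratios_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of FRET-ratio distributions.

    Returns (D, p).  Exact/asymptotic p-value selection follows sample size.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must have n >= 2")
    res = ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
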