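"""Rendering of two-channel biosensor movies and spatial test fields."""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.draw import disk

from ..trace import CellTrace


def render_movie(
    traces: list[CellTrace],
    image_shape: tuple[int, int],
    cell_radius: float = 6.0,
    donor_level: float | dict[int, float] = 100.0,
    poisson_noise: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render traces as disks into (donor, acceptor, label) stacks.

    The donor channel is constant per cell (its expression level); the
    acceptor channel is donor times the cell's true ratio at that frame, so a
    noise-free render measures back to the input ratio exactly.  Where two
    disks overlap the higher cell id wins (cells are drawn in ascending id
    order and later draws overwrite).  Labels are uint16, background 0.
    """
    if cell_radius < 2:
        raise ValueError("cell_radius must be >= 2 px")
    h, w = image_shape
    if not traces:
        z = np.zeros((1, h, w))
        return z, z.copy(), np.zeros((1, h, w), dtype=np.uint16)
    all_times = np.unique(np.concatenate([t.times for t in traces]))
    n_frames = len(all_times)
    donor = np.zeros((n_frames, h, w), dtype=float)
    acceptor = np.zeros((n_frames, h, w), dtype=float)
    labels = np.zeros((n_frames, h, w), dtype=np.uint16)
    for tr in sorted(traces, key=lambda t: t.cell_id):
        if tr.xy is None:
            raise ValueError(f"trace {tr.cell_id} has no positions to render")
        level = donor_level[tr.cell_id] if isinstance(donor_level, dict) else donor_level
        frame_idx = np.searchsorted(all_times, tr.times)
        for k, fi in enumerate(frame_idx):
            x, y = tr.xy[k]
            if not (cell_radius <= x < w - cell_radius and cell_radius <= y < h - cell_radius):
                raise ValueError(f"cell {tr.cell_id} leaves the frame at t={tr.times[k]}")
            rr, cc = disk((y, x), cell_radius, shape=(h, w))
            donor[fi, rr, cc] = level
            acceptor[fi, rr, cc] = level * tr.ratio[k]
            labels[fi, rr, cc] = tr.cell_id
    if poisson_noise:
        rng = np.random.default_rng() if rng is None else rng
        donor = rng.poisson(donor).astype(float)
        acceptor = rng.poisson(acceptor).astype(float)
    return donor, acceptor, labels


def simulate_spatial_field(
    kind: str,
    image_shape: tuple[int, int] = (256, 256),
    um_per_px: float = 2.0,
    length_scale_um: float = 200.0,
    base_ratio: float = 1.5,
    amp_ratio: float = 1.0,
    donor_level: float = 100.0,
    wound_halfwidth_px: int = 40,
    tumor_radius_px: Optional[int] = None,
    n_frames: int = 1,
    onset_frame: int = 0,
    n_nuclei: int = 0,
    density_ramp: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Synthetic scratch or tumor field with a known edge-decaying ratio.

    The FRET ratio decays from the tissue edge into the bulk::

        ratio(d) = base + amp * exp(-d / length_scale)

    with d the inward distance (μm) from the wound edge (``kind="scratch"``,
    a vertical cell-free band at the image center) or from the tumor outline
    (``kind="tumor"``, a centered disk).  For tumors, optional nuclei are
    sampled with probability increasing linearly toward the center by
    ``density_ramp`` (0 = uniform).  Frames before ``onset_frame`` carry a
    flat ratio, so gradient-onset timing is recoverable.

    Returns a dict with donor/acceptor stacks, the region mask, nuclei
    centroids and the generating truth.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    if length_scale_um <= 0:
        raise ValueError("length scale must be > 0")
    if kind == "scratch":
        mask = np.ones((h, w), dtype=bool)
        c = w // 2
        mask[:, c - wound_halfwidth_px : c + wound_halfwidth_px] = False
    elif kind == "tumor":
        r = tumor_radius_px or min(h, w) // 2 - 4
        yy, xx = np.mgrid[0:h, 0:w]
        mask = (yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= r ** 2
    else:
        raise ValueError("kind must be 'scratch' or 'tumor'")
    d_px = ndimage.distance_transform_edt(mask)
    d_um = d_px * um_per_px
    ratio_grad = base_ratio + amp_ratio * np.exp(-d_um / length_scale_um)
    ratio_flat = np.full((h, w), base_ratio)
    donor = np.zeros((n_frames, h, w))
    acceptor = np.zeros((n_frames, h, w))
    for f in range(n_frames):
        r_img = ratio_grad if f >= onset_frame else ratio_flat
        if noise_sd > 0:
            r_img = r_img + rng.normal(0, noise_sd, size=(h, w))
        donor[f][mask] = donor_level
        acceptor[f][mask] = donor_level * r_img[mask]
    nuclei = np.zeros((0, 2))
    if n_nuclei > 0:
        ys, xs = np.nonzero(mask)
        d_edge = d_um[ys, xs]
        depth = d_edge / d_edge.max() if d_edge.max() > 0 else d_edge
        wgt = 1.0 + density_ramp * depth
        wgt = np.clip(wgt, 0, None)
        p = wgt / wgt.sum()
        idx = rng.choice(len(ys), size=n_nuclei, p=p)
        nuclei = np.column_stack([xs[idx], ys[idx]]).astype(float)
    return {
        "donor": donor,
        "acceptor": acceptor,
        "mask": mask,
        "nuclei_xy": nuclei,
        "truth": {
            "kind": kind,
            "length_scale_um": length_scale_um,
            "base_ratio": base_ratio,
            "amp_ratio": amp_ratio,
            "um_per_px": um_per_px,
            "onset_frame": onset_frame,
            "density_ramp": density_ramp,
        },
    }
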