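"""Photon-limited TCSPC decay histograms with a measured IRF."""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def bin_centers(n_bins: int, bin_width: float) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) * bin_width


def gaussian_irf(n_bins: int, bin_width: float, center_ns: float = 1.0, sigma_ns: float = 0.2) -> np.ndarray:
    """Normalized Gaussian instrument response on the TCSPC bin grid."""
    t = bin_centers(n_bins, bin_width)
    irf = np.exp(-0.5 * ((t - center_ns) / sigma_ns) ** 2)
    return irf / irf.sum()


def delta_irf(n_bins: int) -> np.ndarray:
    irf = np.zeros(n_bins)
    irf[0] = 1.0
    return irf


def expected_decay(
    taus: Sequence[float],
    amplitudes: Sequence[float],
    irf: np.ndarray,
    photons: float,
    n_bins: int,
    bin_width: float,
) -> np.ndarray:
    """IRF-convolved multi-exponential decay scaled to ``photons`` counts."""
    taus = np.asarray(taus, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be > 0")
    if np.any(amps < 0) or abs(amps.sum() - 1.0) > 1e-9:
        raise ValueError("amplitudes must be >= 0 and sum to 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if photons < 1:
        raise ValueError("photons must be >= 1")
    t = bin_centers(n_bins, bin_width)
    decay = np.zeros(n_bins)
    for a, tau in zip(amps, taus):
        decay += a * np.exp(-t / tau)
    model = np.convolve(irf, decay)[:n_bins]
    return model / model.sum() * photons


def simulate_tcspc_pixel(
    taus: Sequence[float],
    amplitudes: Sequence[float],
    irf: np.ndarray,
    photons: float,
    n_bins: int,
    bin_width: float,
    rng: Optional[np.random.Generator] = None,
    poisson: bool = True,
) -> np.ndarray:
    """One pixel's photon-count histogram (Poisson-sampled unless disabled)."""
    mu = expected_decay(taus, amplitudes, irf, photons, n_bins, bin_width)
    if not poisson:
        return mu
    rng = np.random.default_rng() if rng is None else rng
    return rng.poisson(mu).astype(float)


def simulate_tcspc_cube(
    tau_map: np.ndarray,
    irf: np.ndarray,
    photons: float,
    n_bins: int,
    bin_width: float,
    taus_by_region: dict[int, tuple[tuple[float, float], tuple[float, float]]],
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Decay cube (H, W, n_bins) from a per-pixel region map.

    ``tau_map`` holds integer region codes; ``taus_by_region`` maps each code
    to ((tau1, tau2), (a1, a2)).  All pixels of one region share the expected
    histogram; Poisson noise is drawn independently per pixel.
    """
    rng = np.random.default_rng() if rng is None else rng
    h, w = tau_map.shape
    cube = np.zeros((h, w, n_bins))
    for code, (taus, amps) in taus_by_region.items():
        mu = expected_decay(taus, amps, irf, photons, n_bins, bin_width)
        m = tau_map == code
        cube[m] = rng.poisson(np.broadcast_to(mu, (int(m.sum()), n_bins)))
    return cube
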