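"""TCSPC lifetime fitting: IRF-convolved bi-exponential decays per pixel.

The per-pixel model is

    m(t) = scale * [ IRF(t - shift) ⊛ (f1 e^{-t/τ1} + (1-f1) e^{-t/τ2}) ] + bg

fitted by Poisson-weighted least squares (Neyman weights, counts+1
regularized).  Nonlinear parameters are (τ1, τ2, f1, shift); the scale and
constant background enter linearly and are solved in closed form at every
step.  Amplitude-weighted mean lifetime is a1 τ1 + a2 τ2 with τ1 <= τ2
enforced by sorting.  The map pipeline follows the standard FLIM recipe:
3x3 spatial averaging, a strict >100-photon validity mask, then a per-pixel
fit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

PHOTON_THRESHOLD = 100.0


def convolve_irf(irf: np.ndarray, decay: np.ndarray) -> np.ndarray:
    """Causal discrete convolution truncated to the bin grid."""
    n = len(decay)
    return np.convolve(irf, decay)[:n]


def spatial_bin(cube: np.ndarray) -> np.ndarray:
    """3x3 spatial averaging per time bin; edge pixels use available neighbors."""
    if cube.shape[0] < 3 or cube.shape[1] < 3:
        raise ValueError("cube must be at least 3x3 pixels")
    sums = ndimage.uniform_filter(cube, size=(3, 3, 1), mode="constant", cval=0.0) * 9.0
    ones = np.ones(cube.shape[:2])
    counts = ndimage.uniform_filter(ones, size=3, mode="constant", cval=0.0) * 9.0
    return sums / counts[:, :, None]


def photon_mask(cube: np.ndarray, threshold: float = PHOTON_THRESHOLD) -> np.ndarray:
    """Valid pixels have an integrated signal strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return cube.sum(axis=-1) > threshold


def _shifted_irf(irf: np.ndarray, shift_bins: float) -> np.ndarray:
    """IRF shifted by a fractional number of bins (linear interpolation)."""
    n = len(irf)
    x = np.arange(n) - shift_bins
    return np.interp(x, np.arange(n), irf, left=0.0, right=0.0)


@dataclass
class BiexpFit:
    tau1: float
    tau2: float
    a1: float
    a2: float
    mean_tau: float
    chi2: float
    scale: float = np.nan
    background: float = np.nan
    shift_ns: float = 0.0
    converged: bool = True
    mono: bool = False
    message: str = ""


def _initial_guesses(decay: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """Automatic (τ1, τ2) guesses from the decay's tail and early log-slopes.

    The slow lifetime comes from a log-linear fit over the tail (last usable
    30% after the peak); the fast one from the first 15% after the peak.
    Both are seed-independent and clipped to the observation window.
    """
    peak = int(np.argmax(decay))
    bg = max(np.median(decay[: max(peak // 2, 1)]) if peak > 3 else 0.0, 0.0)
    y = np.clip(decay - bg, 1e-9, None)
    post = np.arange(peak + 1, len(decay))
    if len(post) < 6:
        return t[-1] / 10, t[-1] / 3
    tail = post[int(len(post) * 0.6):]
    early = post[: max(int(len(post) * 0.15), 3)]

    def slope_tau(idx):
        good = idx[y[idx] > max(1.0, 1e-6)]
        if len(good) < 3:
            return None
        s = np.polyfit(t[good], np.log(y[good]), 1)[0]
        return -1.0 / s if s < 0 else None

    tau2 = slope_tau(tail) or t[-1] / 4
    tau1 = slope_tau(early) or tau2 / 3
    tau1 = float(np.clip(tau1, t[1] / 2, t[-1]))
    tau2 = float(np.clip(tau2, tau1 * 1.2, t[-1] * 2))
    return tau1, tau2


def fit_biexp_irf(
    decay: np.ndarray,
    irf: np.ndarray,
    bin_width: float,
    fit_shift: bool = True,
    max_nfev: int = 200,
) -> BiexpFit:
    """Poisson-weighted bi-exponential fit of one decay histogram."""
    decay = np.asarray(decay, dtype=float)
    n = len(decay)
    t = (np.arange(n) + 0.5) * bin_width
    w = 1.0 / np.sqrt(decay + 1.0)  # Neyman weights, regularized

    def shapes(tau1, tau2, f1, shift_bins):
        irf_s = _shifted_irf(irf, shift_bins) if fit_shift else irf
        mix = f1 * np.exp(-t / tau1) + (1 - f1) * np.exp(-t / tau2)
        return convolve_irf(irf_s, mix)

    def solve_linear(shape):
        # weighted lsq for scale & background given the unit shape
        a = np.column_stack([shape, np.ones(n)]) * w[:, None]
        b = decay * w
        coef, *_ = np.linalg.lstsq(a, b, rcond=None)
        return coef  # (scale, background)

    def residuals(theta):
        tau1, tau2 = np.exp(theta[0]), np.exp(theta[1])
        f1 = 1.0 / (1.0 + np.exp(-theta[2]))
        shift = theta[3] if fit_shift else 0.0
        sh = shapes(tau1, tau2, f1, shift)
        scale, bg = solve_linear(sh)
        return (scale * sh + bg - decay) * w

    tau1_0, tau2_0 = _initial_guesses(decay, t)
    theta0 = [np.log(tau1_0), np.log(tau2_0), 0.0, 0.0][: 4 if fit_shift else 3]
    try:
        res = least_squares(residuals, theta0, method="lm" if not fit_shift else "trf",
                            max_nfev=max_nfev)
    except Exception as err:  # pragma: no cover
        return BiexpFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                        converged=False, message=str(err))
    tau1, tau2 = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    f1 = float(1.0 / (1.0 + np.exp(-res.x[2])))
    shift = float(res.x[3]) if fit_shift else 0.0
    if tau1 > tau2:  # enforce τ1 <= τ2
        tau1, tau2, f1 = tau2, tau1, 1.0 - f1
    sh = shapes(tau1, tau2, f1, shift)
    scale, bg = solve_linear(sh)
    chi2 = float(np.sum(residuals(res.x) ** 2)) / max(n - len(res.x) - 2, 1)
    mono = tau2 / max(tau1, 1e-12) < 1.05
    if mono:  # degenerate: collapse to a mono-exponential
        f1, tau2 = 1.0, tau1
    a1, a2 = f1, 1.0 - f1
    mean_tau = a1 * tau1 + a2 * tau2
    return BiexpFit(tau1=tau1, tau2=tau2, a1=a1, a2=a2, mean_tau=mean_tau,
                    chi2=chi2, scale=float(scale), background=float(bg),
                    shift_ns=shift * bin_width, converged=res.success, mono=mono)


@dataclass
class LifetimeMap:
    mean_tau: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    chi2: np.ndarray
    valid: np.ndarray
    photon_count: np.ndarray


def lifetime_map(
    cube: np.ndarray,
    irf: np.ndarray,
    bin_width: float,
    threshold: float = PHOTON_THRESHOLD,
    smooth: bool = True,
    fit_shift: bool = False,
) -> LifetimeMap:
    """Smooth → mask → fit pipeline over a decay cube (H, W, n_bins).

    Invalid (sub-threshold or non-converged) pixels carry NaN lifetimes.
    """
    if cube.shape[-1] != len(irf):
        raise ValueError("cube and IRF must share the time-bin grid")
    work = spatial_bin(cube) if smooth else np.asarray(cube, dtype=float)
    valid = photon_mask(work, threshold)
    h, w = valid.shape
    nan = np.full((h, w), np.nan)
    out = LifetimeMap(mean_tau=nan.copy(), tau1=nan.copy(), tau2=nan.copy(),
                      a1=nan.copy(), a2=nan.copy(), chi2=nan.copy(),
                      valid=valid.copy(), photon_count=work.sum(axis=-1))
    for y, x in zip(*np.nonzero(valid)):
        fit = fit_biexp_irf(work[y, x], irf, bin_width, fit_shift=fit_shift)
        if not fit.converged or not np.isfinite(fit.mean_tau):
            out.valid[y, x] = False
            continue
        out.mean_tau[y, x] = fit.mean_tau
        out.tau1[y, x] = fit.tau1
        out.tau2[y, x] = fit.tau2
        out.a1[y, x] = fit.a1
        out.a2[y, x] = fit.a2
        out.chi2[y, x] = fit.chi2
    return out
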