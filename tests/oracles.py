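"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the glucose ODE is
re-integrated with scipy's adaptive solver (piecewise across media
switches), and the one-phase decay rate is recovered by profile grid search
over k with the linear parameters solved in closed form, refined by bounded
scalar minimization.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar


def ode_ratio_oracle(scen, model, cell) -> np.ndarray:
    """Noiseless ratio trace via piecewise adaptive integration."""
    full_t = scen.times
    switches = [t for t, _ in scen.glucose_media_schedule]
    bounds = switches + [full_t[-1]]
    vals = {0.0: cell.g0}
    gcur = cell.g0
    for (a, b) in zip(bounds[:-1], bounds[1:]):
        ge = float(scen.media_glucose(a)[0])

        def rhs(t, y, ge=ge):
            return (cell.vup * ge / (scen.k_media + ge)
                    - cell.vcon * y[0] / (scen.km_consumption + y[0]))

        te = full_t[(full_t > a) & (full_t <= b)]
        sol = solve_ivp(rhs, (a, b), [gcur], t_eval=te, rtol=1e-11, atol=1e-13)
        for tt, gg in zip(te, sol.y[0]):
            vals[tt] = gg
        gcur = sol.y[0][-1] if len(sol.y[0]) else gcur
    gs = np.array([vals[t] for t in full_t])
    return np.asarray(model.response(gs))


def grid_decay_rate(times: np.ndarray, values: np.ndarray, t0: float, t_end: float,
                    k_lo: float = 1e-3, k_hi: float = 1.0, n_grid: int = 10_000) -> float:
    """Profile least squares over k on a grid, parabola-refined.

    For each k the plateau/span enter linearly and are solved in closed form
    from the 2x2 normal equations.
    """
    m = (times >= t0 - 1e-12) & (times <= t_end + 1e-12)
    t, y = times[m] - t0, values[m]
    n = len(t)
    sy = y.sum()

    def rss(k: float) -> float:
        e = np.exp(-k * t)
        s1, s2, sey = e.sum(), (e * e).sum(), (e * y).sum()
        det = n * s2 - s1 * s1
        if det <= 1e-14:
            return np.inf
        plateau = (s2 * sy - s1 * sey) / det
        span = (n * sey - s1 * sy) / det
        r = plateau + span * e - y
        return float(r @ r)

    ks = np.linspace(k_lo, k_hi, n_grid)
    # vectorized grid pass
    E = np.exp(-np.outer(ks, t))
    s1 = E.sum(axis=1)
    s2 = (E * E).sum(axis=1)
    sey = E @ y
    det = n * s2 - s1 * s1
    plateau = (s2 * sy - s1 * sey) / det
    span = (n * sey - s1 * sy) / det
    rss_grid = ((plateau[:, None] + span[:, None] * E - y) ** 2).sum(axis=1)
    i = int(np.argmin(rss_grid))
    lo, hi = ks[max(i - 1, 0)], ks[min(i + 1, n_grid - 1)]
    res = minimize_scalar(rss, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def brute_force_ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """ECDF sup-distance by direct evaluation at every pooled point."""
    pts = np.concatenate([a, b])
    fa = np.array([(a <= x).mean() for x in pts])
    fb = np.array([(b <= x).mean() for x in pts])
    return float(np.max(np.abs(fa - fb)))


def brute_force_radial_ratio(donor, acceptor, region, d_um, edges):
    """Pixel-loop ratio-of-sums per distance bin."""
    n_bins = len(edges) - 1
    don = np.zeros(n_bins)
    acc = np.zeros(n_bins)
    h, w = region.shape
    for yy in range(h):
        for xx in range(w):
            if not region[yy, xx]:
                continue
            b = int(np.searchsorted(edges, d_um[yy, xx], side="right") - 1)
            b = min(max(b, 0), n_bins - 1)
            don[b] += donor[yy, xx]
            acc[b] += acceptor[yy, xx]
    out = np.full(n_bins, np.nan)
    nz = don > 0
    out[nz] = acc[nz] / don[nz]
    return out


def brute_force_convolution(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """O(n^2) causal discrete convolution truncated to len(b)."""
    n = len(b)
    out = np.zeros(n)
    for i in range(n):
        for j in range(i + 1):
            if j < len(a):
                out[i] += a[j] * b[i - j]
    return out
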