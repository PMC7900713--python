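"""Per-pixel fluorescence lifetimes from simulated TCSPC decay cubes.

A two-region field (donor lifetime shortened by FRET in the high-glucose
region) is simulated at ~10^4 photons/pixel with a Gaussian IRF, smoothed
3x3, masked at >100 photons, and fitted per pixel with an IRF-convolved
double-exponential; region medians are compared to the generating
lifetimes.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from metaboscope.flim import lifetime_map
from metaboscope.sim.tcspc import gaussian_irf, simulate_tcspc_cube

N_BINS = 256
BIN_WIDTH = 11.1 / 256  # ns (90 MHz excitation period over 256 bins)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--size", type=int, default=32)
    ap.add_argument("--out", type=Path, default=Path("results/flim_summary.csv"))
    args = ap.parse_args()
    irf = gaussian_irf(N_BINS, BIN_WIDTH, center_ns=1.0, sigma_ns=0.2)
    region = np.zeros((args.size, args.size), int)
    region[:, args.size // 2:] = 1  # high glucose: more FRET, shorter lifetime
    cube = simulate_tcspc_cube(
        region, irf, 1e4, N_BINS, BIN_WIDTH,
        {0: ((2.4, 2.4), (1.0, 0.0)), 1: ((1.5, 3.0), (0.7, 0.3))},
        rng=np.random.default_rng(args.seed))
    lm = lifetime_map(cube, irf, BIN_WIDTH, threshold=100)
    low = np.nanmedian(lm.mean_tau[region == 0])
    high = np.nanmedian(lm.mean_tau[region == 1])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"n_valid": int(lm.valid.sum()),
                   "median_tau_low_glucose_ns": low,
                   "median_tau_high_glucose_ns": high}]).to_csv(args.out, index=False)
    print(f"{int(lm.valid.sum())} / {region.size} pixels fitted")
    print(f"low-glucose region:  median mean lifetime {low:.3f} ns (generated 2.40)")
    print(f"high-glucose region: median mean lifetime {high:.3f} ns "
          f"(generated 0.7*1.5 + 0.3*3.0 = 1.95)")


if __name__ == "__main__":
    main()
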