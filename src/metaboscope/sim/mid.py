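"""Simulated mass-isotopomer distributions from a 13C-tracer experiment.

Each molecule's carbon skeleton acquires tracer label per-carbon with
probability ``p`` (binomial transfer model); the remaining unlabeled carbons
carry naturally abundant 13C with probability ``q`` (1.07% by default).  The
observed MID is the normalized histogram of total heavy-carbon counts.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

NATURAL_ABUNDANCE_13C = 0.0107


def simulate_mid(
    n_carbons: int,
    labeled_fraction: float,
    nat_abund: float = NATURAL_ABUNDANCE_13C,
    n_molecules: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Raw (uncorrected) MID vector M+0..M+n, normalized to sum 1."""
    if not (0.0 <= labeled_fraction <= 1.0 and 0.0 <= nat_abund <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    labeled = rng.binomial(n_carbons, labeled_fraction, size=n_molecules)
    natural = rng.binomial(n_carbons - labeled, nat_abund)
    counts = np.bincount(labeled + natural, minlength=n_carbons + 1).astype(float)
    return counts / counts.sum()
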