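"""Shared small utilities: score binning, seed derivation, validation helpers."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("adaptint")

#: number of uniform score bins on [0, 1] shared by the effectiveness table,
#: the conditional-mean reward predictor and the tabular policy state key
DEFAULT_SCORE_BINS = 10


def check_finite(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr!r}")
    return arr


def discretize_score(s: float, n_bins: int = DEFAULT_SCORE_BINS) -> int:
    """Uniform binning of a score on [0, 1] into ``n_bins`` half-open bins.

    Bins are [lo, hi) except the final bin, which is closed at 1.0.
    Scores outside [0, 1] are clipped (with a log warning): engagement and
    skill scores live on [0, 1] by convention.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not np.isfinite(s):
        raise ValueError("score must be finite")
    if s < 0.0 or s > 1.0:
        logger.warning("score %.4g outside [0, 1]; clipping", s)
        s = min(max(s, 0.0), 1.0)
    b = int(s * n_bins)
    return min(b, n_bins - 1)


def child_seed(master_seed: int, child_index: int) -> np.random.SeedSequence:
    """Per-child seed derived from the master seed.

    Uses numpy's SeedSequence spawn-key mechanism (a splitmix-style
    derivation): the cohort is reproducible from (master_seed, child_index)
    alone, and children are statistically independent.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(child_index,))
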