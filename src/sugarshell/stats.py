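"""Block-bootstrap uncertainty estimation for time-averaged observables.

MD frames are correlated, so the naive (block length 1) bootstrap
underestimates the standard error of a trajectory mean. The block
bootstrap resamples contiguous blocks with replacement; with block
lengths beyond the correlation time it converges to an honest error bar.
The default block length is 1 — callers analysing correlated series
should raise it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["BootstrapResult", "bootstrap_mean"]


@dataclass
class BootstrapResult:
    observable: str
    mean: float
    stderr: float
    n_resamples: int
    seed: Optional[int]
    block_length: int


def bootstrap_mean(
    series: np.ndarray,
    n_resamples: int = 1000,
    block_length: int = 1,
    seed: Optional[int] = None,
    observable: str = "observable",
) -> BootstrapResult:
    """Bootstrap standard error of the mean of a per-frame series.

    ceil(N / block_length) contiguous blocks are drawn with replacement
    per resample (truncated to length N); the stderr is the standard
    deviation of the resample means. Deterministic under a fixed seed.
    """
    series = np.asarray(series, dtype=float).ravel()
    n = series.size
    if n == 0:
        raise ValueError("empty series")
    if n < 2:
        raise ValueError("series must have at least 2 entries")
    if not 1 <= block_length <= n:
        raise ValueError(f"block_length must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_length))
    starts_max = n - block_length  # inclusive upper bound for block starts
    means = np.empty(n_resamples)
    offsets = np.arange(block_length)
    for r in range(n_resamples):
        starts = rng.integers(0, starts_max + 1, size=n_blocks)
        idx = (starts[:, None] + offsets[None, :]).ravel()[:n]
        means[r] = series[idx].mean()
    return BootstrapResult(
        observable=observable,
        mean=float(series.mean()),
        stderr=float(np.std(means, ddof=1)),
        n_resamples=n_resamples,
        seed=seed,
        block_length=block_length,
    )
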