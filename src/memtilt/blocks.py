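"""Block-averaging error estimation for correlated scalar time series.

For a series of length n and block size b, the series is cut into
``floor(n/b)`` consecutive blocks and ``EE(b) = SD(block means)/sqrt(n_blocks)``.
On uncorrelated data EE(b) is flat in b at SD/sqrt(n); on positively
correlated data it rises with b and plateaus at the true standard error of
the mean once blocks exceed the correlation time.  The summary EE is the
maximum EE over block sizes that still leave >= 10 blocks — a conservative,
deterministic plateau estimate.

Runs are combined with the between-run spread (SD of run means / sqrt(n_runs)),
treating replicate runs as the independent units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BlockStats",
    "RunSummary",
    "block_average",
    "trailing_window_summary",
    "combine_runs",
    "default_block_sizes",
]

_MIN_BLOCKS_FOR_SUMMARY = 10


@dataclass
class BlockStats:
    """Mean and block-averaged error estimate of one scalar series."""

    mean: float
    block_sizes: np.ndarray
    ee: np.ndarray             # EE at each retained block size
    n_blocks: np.ndarray
    summary_ee: float
    n: int                     # series length analysed
    n_effective: float         # implied independent-sample count


@dataclass
class RunSummary:
    """Combination of per-run (mean, EE) summaries."""

    run_means: np.ndarray
    run_ees: np.ndarray
    mean: float
    ee: float
    single_run: bool = False


def default_block_sizes(n: int) -> list[int]:
    """Powers of two from 1 up to n // 10 (always at least [1])."""
    sizes = [1]
    b = 2
    while b <= max(n // 10, 1):
        sizes.append(b)
        b *= 2
    return sizes


def block_average(series: np.ndarray,
                  block_sizes: list[int] | None = None) -> BlockStats:
    """Block-averaging analysis of one scalar series."""
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if n < 2:
        raise ValueError("series must have at least 2 points")
    if block_sizes is None:
        block_sizes = default_block_sizes(n)
    if any(b < 1 for b in block_sizes):
        raise ValueError("block sizes must be >= 1")
    kept_b, kept_ee, kept_nb = [], [], []
    for b in sorted(set(int(b) for b in block_sizes)):
        nb = n // b
        if nb < 2:
            warnings.warn(
                f"block size {b} skipped: fewer than 2 blocks in {n} points",
                stacklevel=2,
            )
            continue
        means = x[: nb * b].reshape(nb, b).mean(axis=1)
        ee = float(np.std(means, ddof=1) / np.sqrt(nb))
        kept_b.append(b)
        kept_ee.append(ee)
        kept_nb.append(nb)
    if not kept_b:
        raise ValueError("no usable block sizes for this series length")
    kept_b = np.array(kept_b)
    kept_ee = np.array(kept_ee)
    kept_nb = np.array(kept_nb)
    eligible = kept_nb >= _MIN_BLOCKS_FOR_SUMMARY
    if np.any(eligible):
        summary = float(kept_ee[eligible].max())
    else:
        warnings.warn(
            "no block size leaves >= 10 blocks; summary EE uses all sizes",
            stacklevel=2,
        )
        summary = float(kept_ee.max())
    var = float(np.var(x, ddof=1))
    n_eff = var / summary**2 if summary > 0 else float(n)
    return BlockStats(mean=float(x.mean()), block_sizes=kept_b, ee=kept_ee,
                      n_blocks=kept_nb, summary_ee=summary, n=n,
                      n_effective=n_eff)


def trailing_window_summary(series: np.ndarray, window: float = 0.5,
                            block_sizes: list[int] | None = None) -> BlockStats:
    """Block-average the trailing *window* fraction of the series."""
    if not 0.0 < window <= 1.0:
        raise ValueError(f"window must be in (0, 1], got {window}")
    x = np.asarray(series, dtype=float).ravel()
    start = int(np.ceil((1.0 - window) * len(x)))
    return block_average(x[start:], block_sizes=block_sizes)


def combine_runs(summaries: list[tuple[float, float]]) -> RunSummary:
    """Combine per-run (mean, EE) pairs.

    With >= 2 runs the combined EE is the between-run spread
    SD(run means)/sqrt(n_runs); a single run keeps its own EE, flagged.
    """
    if not summaries:
        raise ValueError("need at least one run summary")
    means = np.array([m for m, _ in summaries], dtype=float)
    ees = np.array([e for _, e in summaries], dtype=float)
    if len(means) == 1:
        return RunSummary(run_means=means, run_ees=ees, mean=float(means[0]),
                          ee=float(ees[0]), single_run=True)
    ee = float(np.std(means, ddof=1) / np.sqrt(len(means)))
    return RunSummary(run_means=means, run_ees=ees, mean=float(means.mean()),
                      ee=ee, single_run=False)
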