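"""T_MRCA-segment analytics: time discretization, TL-distribution summaries
and the segment-age transition matrix (TM_true).

Segment ages are discretized on a logarithmic grid whose bin ``i`` has lower
boundary ``-8 N_ref ln(1 - i/m)`` (the MSMC-style spacing), so bins track the
quantiles of a pairwise coalescent with effective size ``N_ref``.  TM_true is
purely descriptive here: inference uses the window-diversity analogue in
:mod:`selfkit.sumstats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coalsim import PairSegmentSeries

__all__ = ["TimeGrid", "TransitionMatrixT", "time_grid", "tl_summaries", "tm_true"]


@dataclass(frozen=True)
class TimeGrid:
    """Logarithmic discretization of T_MRCA into ``m`` bins.

    ``boundaries[i] = -8 N_ref ln(1 - i/m)`` for ``i = 0..m-1``; the top bin
    is open-ended.  Bins are half-open ``[boundaries[i], boundaries[i+1])``.
    """

    N_ref: float
    m: int
    boundaries: np.ndarray

    def bin_of(self, ages) -> np.ndarray:
        """Bin index for each age (ages of exactly 0 map to bin 0)."""
        ages = np.asarray(ages, dtype=float)
        return np.clip(
            np.searchsorted(self.boundaries, ages, side="right") - 1, 0, self.m - 1
        )


def time_grid(N_ref: float, m: int) -> TimeGrid:
    if m < 2:
        raise ValueError("need at least two bins")
    if N_ref <= 0:
        raise ValueError("reference size must be positive")
    i = np.arange(m)
    bounds = -8.0 * N_ref * np.log1p(-i / m)
    return TimeGrid(N_ref=N_ref, m=m, boundaries=bounds)


@dataclass
class TransitionMatrixT:
    """Row-stochastic matrix of age-bin transitions between adjacent segments.

    Rows with no observations are all-zero and listed in ``empty_rows``.
    """

    grid: TimeGrid
    counts: np.ndarray
    probs: np.ndarray
    empty_rows: np.ndarray

    def to_tsv(self, path) -> None:
        header = "\t".join(f"ge_{b:.1f}" for b in self.grid.boundaries)
        np.savetxt(path, self.probs, delimiter="\t", header=header, comments="")


def tl_summaries(series: PairSegmentSeries, grid: TimeGrid) -> dict:
    """Joint age-length summaries of a segment series.

    Returns the covariance of (log10 age, log10 length) pairs, the per-bin
    mean log10 length, and marginal histograms of ages (per grid bin) and of
    log10 lengths.  The covariance of a single segment is undefined and
    reported as NaN.
    """
    if len(series) == 0:
        raise ValueError("empty segment series")
    la = np.log10(series.tmrcas)
    ll = np.log10(series.lengths)
    if len(series) >= 2:
        cov = float(np.cov(la, ll, ddof=1)[0, 1])
    else:
        cov = math.nan
    bins = grid.bin_of(series.tmrcas)
    mean_log_len = np.full(grid.m, np.nan)
    age_hist = np.zeros(grid.m, dtype=np.int64)
    for b in range(grid.m):
        sel = bins == b
        age_hist[b] = int(sel.sum())
        if sel.any():
            mean_log_len[b] = float(ll[sel].mean())
    len_hist, len_edges = np.histogram(ll, bins=20)
    return {
        "n_segments": len(series),
        "cov_logage_loglength": cov,
        "mean_log_length_per_bin": mean_log_len,
        "age_bin_counts": age_hist,
        "log_length_hist": (len_hist, len_edges),
    }


def tm_true(series: PairSegmentSeries, grid: TimeGrid) -> TransitionMatrixT:
    """Transition matrix of discretized ages between adjacent segments.

    ``counts[a, b]`` is the number of adjacent segment pairs whose ages fall
    in bins ``a`` then ``b``, scanning the chromosome left to right; ``probs``
    are the row-normalized counts.
    """
    if len(series) < 2:
        raise ValueError("need at least two segments")
    bins = grid.bin_of(series.tmrcas)
    counts = np.zeros((grid.m, grid.m), dtype=np.int64)
    np.add.at(counts, (bins[:-1], bins[1:]), 1)
    row_sums = counts.sum(axis=1)
    probs = np.zeros_like(counts, dtype=float)
    nonzero = row_sums > 0
    probs[nonzero] = counts[nonzero] / row_sums[nonzero, None]
    return TransitionMatrixT(
        grid=grid, counts=counts, probs=probs, empty_rows=np.flatnonzero(~nonzero)
    )
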