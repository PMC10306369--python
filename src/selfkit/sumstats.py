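"""ABC summary statistics: unfolded SFS, discretized LD-decay and the
window-diversity transition matrix (TM_win).

TM_win is the observable analogue of the segment-age transition matrix: the
number of pairwise differences is summed in non-overlapping windows of size
``ω`` (10 kb throughout) for a sample of size two, each window's count is
classified against a frozen set of diversity-class edges, and the matrix of
adjacent-window class transitions is recorded.  If ``ω`` is smaller than the
clusters of old segments left by a transition to selfing, TM_win captures
both their excess diversity and their spatial clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .coalsim import HaplotypeAlignment, RngState

__all__ = [
    "DEFAULT_LD_BREAKPOINTS",
    "LDBins",
    "WindowSeries",
    "SummaryVector",
    "unfolded_sfs",
    "ld_decay",
    "window_diversity",
    "tm_win",
    "summary_vector",
    "combine_summaries",
]

#: physical-distance breakpoints (bp) for the LD-decay discretization
DEFAULT_LD_BREAKPOINTS = (6105, 11379, 21209, 39531, 73680, 137328, 255958, 477066, 889175)

#: windows size ω for pairwise-diversity windows (bp)
DEFAULT_WINDOW_SIZE = 10_000

#: haplotype pairs per dataset entering the TM_win average
MAX_TM_PAIRS = 15


@dataclass(frozen=True)
class LDBins:
    """LD-decay discretization: pairs at distance in ``[bp_j, bp_{j+1})`` fall
    in bin ``j``; distances below the first or at/above the last breakpoint
    are excluded."""

    breakpoints: tuple[int, ...] = DEFAULT_LD_BREAKPOINTS
    max_snps: int = 10_000
    max_pairs: int = 200_000

    def __post_init__(self):
        bp = tuple(self.breakpoints)
        if len(bp) < 2 or any(b <= a for a, b in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be >= 2 and strictly increasing")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def n_bins(self) -> int:
        return len(self.breakpoints) - 1


@dataclass
class WindowSeries:
    """Ordered pairwise-difference counts in non-overlapping windows."""

    window_size: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("window counts must be non-negative")


@dataclass
class SummaryVector:
    """Named, ordered summary-statistic vector (one dataset, one spec)."""

    names: list[str]
    values: np.ndarray
    spec: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.names) + "\n")
            fh.write("\t".join(f"{v:.10g}" for v in self.values) + "\n")


def unfolded_sfs(aln: HaplotypeAlignment) -> np.ndarray:
    """Unfolded site frequency spectrum: entry ``k-1`` is the number of sites
    with derived-allele count ``k`` (``k = 1..n-1``)."""
    n = aln.n_hap
    if n < 2:
        raise ValueError("need at least two haplotypes")
    counts = aln.derived_matrix.sum(axis=0)
    sfs = np.bincount(counts, minlength=n + 1)[1:n]
    return sfs.astype(np.int64)


def ld_decay(
    aln: HaplotypeAlignment, bins: LDBins, rng: RngState
) -> tuple[np.ndarray, np.ndarray]:
    """Mean haplotype ``r²`` per physical-distance bin.

    A subset of at most ``bins.max_snps`` segregating sites is drawn without
    replacement; site pairs (capped at ``bins.max_pairs``) are binned by
    distance and ``r² = D²/(p_A(1-p_A) p_B(1-p_B))`` accumulated.  Returns
    ``(means, missing)`` where bins without any pair have mean 0 and missing
    flag 1.
    """
    nb = bins.n_bins
    means = np.zeros(nb)
    missing = np.ones(nb)
    seg = aln.drop_invariant()
    if seg.n_sites < 2:
        return means, missing
    g = rng.generator()
    if seg.n_sites > bins.max_snps:
        keep = np.sort(g.choice(seg.n_sites, bins.max_snps, replace=False))
        pos = seg.positions[keep]
        mat = seg.derived_matrix[:, keep]
    else:
        pos = seg.positions
        mat = seg.derived_matrix
    S = len(pos)
    n_total = S * (S - 1) // 2
    if n_total <= bins.max_pairs:
        ii, jj = np.triu_indices(S, k=1)
    else:
        ii = g.integers(0, S, bins.max_pairs)
        jj = g.integers(0, S, bins.max_pairs)
        ii, jj = np.minimum(ii, jj), np.maximum(ii, jj)
        ok = ii != jj
        ii, jj = ii[ok], jj[ok]
    dist = pos[jj] - pos[ii]
    which = np.searchsorted(bins.breakpoints, dist, side="right") - 1
    ok = (which >= 0) & (which < nb)
    ii, jj, which = ii[ok], jj[ok], which[ok]
    if len(ii) == 0:
        return means, missing
    n = mat.shape[0]
    rows = np.ascontiguousarray(mat.T)  # site-major for fast pair gathers
    p = rows.mean(axis=1)
    pA, pB = p[ii], p[jj]
    pAB = np.einsum("ij,ij->i", rows[ii], rows[jj], dtype=np.int64) / n
    D = pAB - pA * pB
    r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    sums = np.bincount(which, weights=r2, minlength=nb)
    nums = np.bincount(which, minlength=nb)
    got = nums > 0
    means[got] = sums[got] / nums[got]
    missing[got] = 0.0
    return means, missing


def window_diversity(aln: HaplotypeAlignment, window_size: int = DEFAULT_WINDOW_SIZE
                     ) -> WindowSeries:
    """Pairwise-difference counts per non-overlapping window for two
    haplotypes; the trailing partial window is dropped."""
    if aln.n_hap != 2:
        raise ValueError("window diversity is defined for exactly two haplotypes")
    if window_size < 1:
        raise ValueError("window size must be >= 1")
    n_win = aln.seq_length // window_size
    if n_win < 1:
        raise ValueError("window size exceeds the sequence length")
    diff_pos = aln.positions[aln.derived_matrix[0] != aln.derived_matrix[1]]
    counts = np.bincount(
        np.minimum(diff_pos // window_size, n_win).astype(np.int64), minlength=n_win + 1
    )[:n_win] if len(diff_pos) else np.zeros(n_win, dtype=np.int64)
    # differences in the dropped trailing partial window were clipped into the
    # sentinel bin above and discarded
    return WindowSeries(window_size=int(window_size), counts=counts)


def tm_win(ws: WindowSeries, class_edges) -> np.ndarray:
    """Transition matrix of diversity classes between adjacent windows.

    Window counts are classified by half-open intervals against
    ``class_edges`` (``k = len(edges) + 1`` classes); entry ``(a, b)`` is the
    proportion of adjacent window pairs with classes ``a`` then ``b``.
    """
    edges = np.asarray(class_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("class edges must be strictly increasing")
    if len(ws.counts) < 2:
        raise ValueError("need at least two windows")
    k = len(edges) + 1
    cls = np.searchsorted(edges, ws.counts, side="right")
    mat = np.zeros((k, k))
    np.add.at(mat, (cls[:-1], cls[1:]), 1.0)
    return mat / (len(ws.counts) - 1)


def _tm_pairs(n_hap: int, rng: np.random.Generator, cap: int = MAX_TM_PAIRS):
    pairs = list(combinations(range(n_hap), 2))
    if len(pairs) <= cap:
        return pairs
    idx = rng.choice(len(pairs), size=cap, replace=False)
    return [pairs[i] for i in sorted(idx)]


VALID_SPECS = ("SFS_LD", "TM_WIN", "SFS_LD_TM_WIN")


def summary_vector(
    aln: HaplotypeAlignment,
    spec: str,
    bins: LDBins,
    class_edges,
    window_size: int,
    rng: RngState,
) -> SummaryVector:
    """Named concatenation of the requested statistics for one dataset.

    Ordering is deterministic: SFS entries, LD bin means, LD missingness
    flags, then the row-major TM_win entries averaged over up to
    ``MAX_TM_PAIRS`` haplotype pairs chosen deterministically by seed.
    """
    spec = spec.upper()
    if spec not in VALID_SPECS:
        raise ValueError(f"spec must be one of {VALID_SPECS}")
    names: list[str] = []
    chunks: list[np.ndarray] = []
    if "SFS_LD" in spec:
        sfs = unfolded_sfs(aln)
        names += [f"sfs_{k}" for k in range(1, aln.n_hap)]
        chunks.append(sfs.astype(float))
        ld, miss = ld_decay(aln, bins, rng.child(1))
        names += [f"ld_{j}" for j in range(bins.n_bins)]
        chunks.append(ld)
        names += [f"ld_miss_{j}" for j in range(bins.n_bins)]
        chunks.append(miss)
    if "TM_WIN" in spec:
        k = len(class_edges) + 1
        g = rng.child(2).generator()
        mats = []
        for i, j in _tm_pairs(aln.n_hap, g):
            ws = window_diversity(aln.pair_view(i, j), window_size)
            mats.append(tm_win(ws, class_edges))
        mean_mat = np.mean(mats, axis=0)
        names += [f"tm_{a}_{b}" for a in range(k) for b in range(k)]
        chunks.append(mean_mat.ravel())
    return SummaryVector(names=names, values=np.concatenate(chunks), spec=spec)


def combine_summaries(vectors: list[SummaryVector]) -> SummaryVector:
    """Element-wise average of per-locus summary vectors (combined statistics
    for a multi-locus dataset)."""
    if not vectors:
        raise ValueError("no vectors to combine")
    names = vectors[0].names
    spec = vectors[0].spec
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError("summary vectors are not alignable")
    values = np.mean([v.values for v in vectors], axis=0)
    return SummaryVector(names=list(names), values=values, spec=spec)
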