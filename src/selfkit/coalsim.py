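"""Simulators for polymorphism data under time-varying selfing.

Three routes to the same model, used to cross-validate one another:

- :func:`simulate_pair` — an exact sequential (SMC') simulator for a sample
  of size two, written directly in real time with the inhomogeneous pairwise
  coalescence rate ``(1+F(t))/(2N(t))`` and the effective pair recombination
  hazard ``2 r(t) (1-F(t))`` integrated along the tree.
- :func:`simulate_sample` — a multi-sample coalescent via msprime, using the
  time change ``dτ = (1-F(t)) dt`` under which the recombination rate is the
  constant raw ``r`` and the effective size is ``N(t)(1-F(t))/(1+F(t))``;
  node times are mapped back through the inverse piecewise-linear change
  before mutations are laid down at the constant per-generation rate ``μ``.
- :func:`simulate_wf_oracle` — an explicit diploid forward Wright-Fisher
  simulation in which each offspring is produced by self-fertilization of a
  single parent with probability ``σ`` or by outcrossing between two distinct
  parents otherwise; the full pedigree and all crossovers are recorded so
  sampled haplotype pairs can be traced to their segment-wise common
  ancestors.  Test-scale only (``N ≤ 2000``, ``L ≤ 100 kb``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import msprime

from .selfing_model import DemographicModel, Epoch

__all__ = [
    "RngState",
    "PairSegmentSeries",
    "HaplotypeAlignment",
    "SampleSimulation",
    "simulate_pair",
    "overlay_mutations",
    "simulate_sample",
    "simulate_wf_oracle",
    "WFRecord",
]

#: multi-sample simulator refuses selfing rates above this (the time change
#: degenerates as F -> 1); the pairwise and WF routes handle sigma = 1.
MAX_SAMPLE_SIGMA = 0.999


@dataclass(frozen=True)
class RngState:
    """Seed wrapper; identical seed and inputs give identical outputs."""

    seed: int

    def __post_init__(self):
        if not (0 <= int(self.seed) < 2**63):
            raise ValueError("seed must be a non-negative 63-bit integer")

    def generator(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def child(self, index: int) -> "RngState":
        """Deterministically derived independent stream."""
        state = np.random.SeedSequence([self.seed, index]).generate_state(1)[0]
        return RngState(int(state) % (2**31 - 1))


@dataclass
class PairSegmentSeries:
    """Contiguous T_MRCA-segments tiling ``[0, seq_length)`` for one pair."""

    seq_length: int
    starts: np.ndarray
    ends: np.ndarray
    tmrcas: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.tmrcas = np.asarray(self.tmrcas, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.tmrcas)):
            raise ValueError("segment arrays must have equal length")
        if len(self.starts):
            if self.starts[0] != 0 or self.ends[-1] != self.seq_length:
                raise ValueError("segments must tile [0, seq_length)")
            if np.any(self.starts[1:] != self.ends[:-1]):
                raise ValueError("segments must be contiguous")
            if np.any(self.ends <= self.starts):
                raise ValueError("segments must have positive length")
            if np.any(self.tmrcas <= 0):
                raise ValueError("tmrca must be positive")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tend\ttmrca\n")
            for a, b, t in zip(self.starts, self.ends, self.tmrcas):
                fh.write(f"{a}\t{b}\t{t:.6f}\n")

    @classmethod
    def from_tsv(cls, path, seq_length=None) -> "PairSegmentSeries":
        data = np.loadtxt(path, skiprows=1, ndmin=2)
        L = int(data[-1, 1]) if seq_length is None else int(seq_length)
        return cls(L, data[:, 0], data[:, 1], data[:, 2])


@dataclass
class HaplotypeAlignment:
    """Phased haplotypes at segregating sites over a known sequence length.

    ``derived_matrix`` is ``n_hap x n_sites`` with 0 for the ancestral and 1
    for the derived allele; ``positions`` are 0-based bp coordinates.
    """

    seq_length: int
    positions: np.ndarray
    derived_matrix: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.derived_matrix = np.asarray(self.derived_matrix, dtype=np.int8)
        if self.derived_matrix.ndim != 2:
            raise ValueError("derived_matrix must be 2-D (haplotypes x sites)")
        if self.derived_matrix.shape[1] != len(self.positions):
            raise ValueError("positions and matrix disagree on site count")
        if len(self.positions) and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < 0
            or self.positions[-1] >= self.seq_length
        ):
            raise ValueError("positions must be strictly increasing within [0, seq_length)")
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(self.n_hap)]

    @property
    def n_hap(self) -> int:
        return self.derived_matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.derived_matrix.shape[1]

    def pair_view(self, i: int, j: int) -> "HaplotypeAlignment":
        """Restriction to two haplotypes, keeping only their segregating sites."""
        sub = self.derived_matrix[[i, j], :]
        keep = sub[0] != sub[1]
        return HaplotypeAlignment(
            self.seq_length,
            self.positions[keep],
            sub[:, keep],
            [self.sample_ids[i], self.sample_ids[j]],
        )

    def subset(self, indices) -> "HaplotypeAlignment":
        """Restriction to a subset of haplotypes (sites left untouched)."""
        indices = list(indices)
        return HaplotypeAlignment(
            self.seq_length,
            self.positions,
            self.derived_matrix[indices, :],
            [self.sample_ids[i] for i in indices],
        )

    def drop_invariant(self) -> "HaplotypeAlignment":
        counts = self.derived_matrix.sum(axis=0)
        keep = (counts > 0) & (counts < self.n_hap)
        return HaplotypeAlignment(
            self.seq_length, self.positions[keep], self.derived_matrix[:, keep],
            list(self.sample_ids),
        )

    def to_vcf(self, path, chrom: str = "1") -> None:
        """Minimal VCF with haploid GT columns; REF is the ancestral allele."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom},length={self.seq_length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_ids)
                + "\n"
            )
            for k, pos in enumerate(self.positions):
                gts = "\t".join(str(int(v)) for v in self.derived_matrix[:, k])
                fh.write(f"{chrom}\t{pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# inhomogeneous-rate primitives (piecewise-constant epochs)
# ---------------------------------------------------------------------------

def _epoch_bounds(model: DemographicModel) -> list[tuple[float, float, Epoch]]:
    out = []
    eps = model.epochs
    for j, e in enumerate(eps):
        hi = eps[j + 1].start_time if j + 1 < len(eps) else math.inf
        out.append((e.start_time, hi, e))
    return out


def _draw_event_time(
    model: DemographicModel,
    start: float,
    rng: np.random.Generator,
    rate_factor: float = 1.0,
    cap: float = math.inf,
) -> float | None:
    """First event of a Poisson process with rate ``rate_factor * (1+F)/(2N)``
    started at ``start``; ``None`` if no event occurs before ``cap``."""
    target = rng.exponential()
    t = start
    for lo, hi, epoch in _epoch_bounds(model):
        if hi <= t:
            continue
        lam = rate_factor * epoch.coal_rate
        top = min(hi, cap)
        if top <= t:
            break
        span = top - t
        if lam * span >= target:
            return t + target / lam
        target -= lam * span
        t = top
        if t >= cap:
            return None
    return None


def _pair_rec_hazard(model: DemographicModel, s: float) -> float:
    """``∫_0^s 2 r(k) (1-F(k)) dk`` — per-bp breakpoint hazard for tmrca s."""
    total = 0.0
    for lo, hi, epoch in _epoch_bounds(model):
        if lo >= s:
            break
        total += 2.0 * epoch.rec_rate * (1.0 - epoch.F) * (min(hi, s) - lo)
    return total


def _draw_detach_time(model: DemographicModel, s: float, rng: np.random.Generator) -> float:
    """Height ``u`` on ``[0, s)`` with density proportional to ``2 r (1-F)``."""
    pieces = []
    for lo, hi, epoch in _epoch_bounds(model):
        if lo >= s:
            break
        top = min(hi, s)
        w = 2.0 * epoch.rec_rate * (1.0 - epoch.F) * (top - lo)
        if w > 0:
            pieces.append((lo, top, w))
    weights = np.array([p[2] for p in pieces])
    k = rng.choice(len(pieces), p=weights / weights.sum())
    lo, top, _ = pieces[k]
    return rng.uniform(lo, top)


# ---------------------------------------------------------------------------
# SMC' pairwise simulator
# ---------------------------------------------------------------------------

def simulate_pair(model: DemographicModel, L: int, rng: RngState) -> PairSegmentSeries:
    """Sequential (SMC') simulation of the T_MRCA-segment series for a pair.

    The first tmrca is drawn from the time-inhomogeneous pairwise coalescent
    with rate ``(1+F(t))/(2N(t))``.  Given the current tmrca ``s``, the
    distance to the next breakpoint is exponential with per-bp hazard
    ``∫_0^s 2 r(k)(1-F(k)) dk``.  At a breakpoint the detached lineage starts
    at a height ``u`` drawn proportional to the local hazard and re-coalesces:
    during ``(u, s)`` with either of the two remaining lineages (total rate
    ``2·(1+F)/(2N)``; hitting its own stump is a silent event that leaves the
    tmrca unchanged, hitting the other branch sets a new, smaller tmrca), and
    above ``s`` with the root lineage at rate ``(1+F)/(2N)``.  Silent events
    do not create segment boundaries: adjacent equal-age pieces are merged.
    """
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    g = rng.generator()

    s = _draw_event_time(model, 0.0, g)
    assert s is not None and s > 0

    bounds: list[float] = [0.0]
    ages: list[float] = []
    x = 0.0
    while True:
        H = _pair_rec_hazard(model, s)
        if H <= 0.0:
            break
        x_new = x + g.exponential(1.0 / H)
        if x_new >= L:
            break
        u = _draw_detach_time(model, s, g)
        t1 = _draw_event_time(model, u, g, rate_factor=2.0, cap=s)
        if t1 is not None:
            new_s = s if g.random() < 0.5 else t1  # own stump (silent) vs other branch
        else:
            new_s = _draw_event_time(model, s, g, rate_factor=1.0)
            assert new_s is not None
        x = x_new
        if new_s != s:
            bounds.append(x_new)
            ages.append(s)
            s = new_s
    ages.append(s)
    bounds.append(float(L))

    # floor continuous breakpoints to integer bp; drop empty pieces and merge
    # adjacent equal ages that dropping may expose
    starts_f = np.floor(np.array(bounds[:-1])).astype(np.int64)
    ends_f = np.floor(np.array(bounds[1:])).astype(np.int64)
    ends_f[-1] = L
    keep = ends_f > starts_f
    starts_f, ends_f = starts_f[keep], ends_f[keep]
    age_arr = np.array(ages)[keep]
    starts_f[0] = 0
    # re-tile: each segment begins where the previous ends
    starts_f[1:] = ends_f[:-1]
    m_starts, m_ends, m_ages = [], [], []
    for a, b, t in zip(starts_f, ends_f, age_arr):
        if m_ages and m_ages[-1] == t:
            m_ends[-1] = b
        else:
            m_starts.append(a)
            m_ends.append(b)
            m_ages.append(t)
    return PairSegmentSeries(int(L), m_starts, m_ends, m_ages)


def overlay_mutations(series: PairSegmentSeries, mu: float, rng: RngState) -> HaplotypeAlignment:
    """Infinite-sites mutation overlay on a pair's segment series.

    Per segment of length ``ℓ`` and age ``s`` the number of pairwise
    differences is Poisson(``2 s μ ℓ``), placed uniformly on integer
    positions within the segment (each on one of the two branches with equal
    probability); collisions at identical positions are dropped.
    """
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    g = rng.generator()
    pos_all, hap_all = [], []
    for a, b, t in zip(series.starts, series.ends, series.tmrcas):
        k = g.poisson(2.0 * t * mu * (b - a))
        if k:
            pos_all.append(g.integers(a, b, size=k))
            hap_all.append(g.integers(0, 2, size=k))
    if not pos_all:
        return HaplotypeAlignment(series.seq_length, [], np.zeros((2, 0), dtype=np.int8))
    pos = np.concatenate(pos_all)
    hap = np.concatenate(hap_all)
    uniq, counts = np.unique(pos, return_counts=True)
    singles = set(uniq[counts == 1])
    keep = np.array([p in singles for p in pos])
    pos, hap = pos[keep], hap[keep]
    order = np.argsort(pos)
    pos, hap = pos[order], hap[order]
    mat = np.zeros((2, len(pos)), dtype=np.int8)
    mat[hap, np.arange(len(pos))] = 1
    return HaplotypeAlignment(series.seq_length, pos, mat)


# ---------------------------------------------------------------------------
# multi-sample simulator (msprime + time rescaling)
# ---------------------------------------------------------------------------

def _rescaled_time_map(model: DemographicModel):
    """Breakpoints of the time change ``dτ = (1-F(t)) dt``.

    Returns (t_breaks, tau_breaks, one_minus_F per epoch)."""
    t_breaks = [e.start_time for e in model.epochs]
    omf = [1.0 - e.F for e in model.epochs]
    tau = [0.0]
    for j in range(1, len(t_breaks)):
        tau.append(tau[-1] + omf[j - 1] * (t_breaks[j] - t_breaks[j - 1]))
    return np.array(t_breaks), np.array(tau), np.array(omf)


@dataclass
class SampleSimulation:
    """Multi-sample simulation result: alignment plus on-demand pair segments."""

    alignment: HaplotypeAlignment
    tree_sequence: object  # tskit.TreeSequence with real-time node ages

    def pair_segments(self, i: int, j: int) -> PairSegmentSeries:
        """T_MRCA-segment series for haplotypes ``i`` and ``j``.

        Adjacent genome intervals with identical pair tmrca are merged, so
        only recombination events consequential for this pair delimit
        segments."""
        ts = self.tree_sequence
        starts, ends, ages = [], [], []
        for tree in ts.trees():
            t = tree.tmrca(i, j)
            a, b = map(int, tree.interval)
            if b <= a:
                continue
            if ages and ages[-1] == t:
                ends[-1] = b
            else:
                starts.append(a)
                ends.append(b)
                ages.append(t)
        return PairSegmentSeries(int(ts.sequence_length), starts, ends, ages)


def simulate_sample(
    model: DemographicModel,
    n: int,
    L: int,
    mu: float,
    rng: RngState,
) -> SampleSimulation:
    """Coalescent simulation of ``n`` haplotypes under time-varying selfing.

    Genealogies follow the coalescent in which the pairwise coalescence rate
    at time ``t`` is ``(1+F(t))/(2N(t))`` and the per-bp recombination rate
    per lineage is ``r (1-F(t))``.  Implemented by simulating in the rescaled
    time ``τ`` with ``dτ = (1-F(t)) dt`` (constant recombination rate ``r``,
    effective size ``N(t)(1-F(t))/(1+F(t))``), mapping node times back
    through the inverse piecewise-linear change, then adding mutations at the
    constant real-time rate ``μ``.
    """
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    if model.max_sigma > MAX_SAMPLE_SIGMA:
        raise ValueError(
            f"simulate_sample supports sigma <= {MAX_SAMPLE_SIGMA}; use "
            "simulate_pair for (nearly) complete selfing"
        )
    r = model.constant_rec_rate()
    t_breaks, tau_breaks, omf = _rescaled_time_map(model)

    dem = msprime.Demography()
    # ploidy-1 samples: pairwise coalescence rate is 1/size, so the rescaled
    # effective size 2 * N (1-F)/(1+F) yields rate (1+F)/(2N(1-F)) in tau-time
    sizes = [2.0 * e.N * (1.0 - e.F) / (1.0 + e.F) for e in model.epochs]
    dem.add_population(name="pop", initial_size=sizes[0])
    for j in range(1, len(sizes)):
        dem.add_population_parameters_change(
            time=tau_breaks[j], initial_size=sizes[j], population="pop"
        )

    g = rng.generator()
    seed_anc, seed_mut = (int(x) for x in g.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples=n,
        demography=dem,
        ploidy=1,
        sequence_length=L,
        recombination_rate=r,
        random_seed=seed_anc,
    )

    # map node times tau -> t through the inverse piecewise-linear change
    tables = ts.dump_tables()
    tau = tables.nodes.time
    idx = np.clip(np.searchsorted(tau_breaks, tau, side="right") - 1, 0, len(omf) - 1)
    tables.nodes.time = t_breaks[idx] + (tau - tau_breaks[idx]) / omf[idx]
    ts_real = tables.tree_sequence()

    mts = msprime.sim_mutations(
        ts_real,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        random_seed=seed_mut,
    )
    positions = mts.tables.sites.position.astype(np.int64)
    if len(positions):
        mat = mts.genotype_matrix().T.astype(np.int8)
    else:
        mat = np.zeros((n, 0), dtype=np.int8)
    aln = HaplotypeAlignment(int(L), positions, mat).drop_invariant()
    return SampleSimulation(alignment=aln, tree_sequence=mts)


# ---------------------------------------------------------------------------
# forward Wright-Fisher oracle
# ---------------------------------------------------------------------------

class WFRecord:
    """Recorded pedigree and crossovers from a forward WF simulation.

    Generation 0 holds the founders (``generations`` before present) and the
    last generation the present-day population.  Per generation we store for
    every offspring its two parents (identical under self-fertilization), for
    every gamete which parental haplotype it starts in, and any crossover
    positions.
    """

    def __init__(self, model: DemographicModel, L: int, generations: int,
                 rng: np.random.Generator):
        self.model = model
        self.L = int(L)
        self.generations = int(generations)
        self._rng = rng
        self.sizes: list[int] = []
        self.parent1: list[np.ndarray] = []
        self.parent2: list[np.ndarray] = []
        self.start_hap: list[np.ndarray] = []
        self.crossovers: list[dict[int, np.ndarray]] = []
        self._run_forward()

    # -- forward pass -------------------------------------------------------
    def _size_at(self, tbp: float) -> int:
        return int(round(self.model.epoch_at(tbp).N))

    def _run_forward(self) -> None:
        G = self.generations
        self.sizes = [self._size_at(G - g) for g in range(G + 1)]
        rng = self._rng
        L = self.L
        # group generations into blocks of constant (n_off, n_par, sigma, r)
        # so the reproduction draws vectorize across generations
        g = 1
        while g <= G:
            epoch = self.model.epoch_at(G - g)
            n_off, n_par = self.sizes[g], self.sizes[g - 1]
            h = g
            while (
                h + 1 <= G
                and self.model.epoch_at(G - (h + 1)) is epoch
                and self.sizes[h + 1] == n_off
                and self.sizes[h] == n_par
            ):
                h += 1
            nb = h - g + 1
            sigma, r = epoch.sigma, epoch.rec_rate
            selfed = rng.random((nb, n_off)) < sigma
            p1 = rng.integers(0, n_par, (nb, n_off))
            p2 = p1.copy()
            out = ~selfed
            if n_par > 1 and out.any():
                alt = rng.integers(0, n_par - 1, int(out.sum()))
                alt += alt >= p1[out]
                p2[out] = alt
            starts = rng.integers(0, 2, (nb, 2 * n_off), dtype=np.uint8)
            ncx = rng.poisson(r * L, (nb, 2 * n_off))
            cx_rows: dict[int, dict[int, np.ndarray]] = {}
            for k, idx in np.argwhere(ncx > 0):
                cx_rows.setdefault(int(k), {})[int(idx)] = np.sort(
                    rng.uniform(0, L, ncx[k, idx])
                )
            for k in range(nb):
                self.parent1.append(p1[k])
                self.parent2.append(p2[k])
                self.start_hap.append(starts[k])
                self.crossovers.append(cx_rows.get(k, {}))
            g = h + 1

    # -- backward tracing ---------------------------------------------------
    def _split_by_crossovers(self, a, b, start_hap, cx):
        """Yield (lo, hi, parent_hap) covering [a, b) given a gamete's crossovers."""
        if len(cx) == 0:
            yield a, b, int(start_hap)
            return
        edges = [a] + [float(p) for p in cx if a < p < b] + [b]
        n_before = int(np.searchsorted(cx, a, side="right"))
        for k in range(len(edges) - 1):
            yield edges[k], edges[k + 1], (int(start_hap) + n_before + k) % 2

    def _step_lineage(self, carriers, p1, p2, start_hap, cx):
        """Move one sample lineage one generation toward the founders."""
        new: dict[tuple[int, int], list[tuple[float, float]]] = {}
        for (ind, hap), intervals in carriers.items():
            gam = 2 * ind + hap
            parent = int(p1[ind]) if hap == 0 else int(p2[ind])
            sh = start_hap[gam]
            gcx = cx.get(gam, ())
            gcx = np.asarray(gcx)
            for a, b in intervals:
                for lo, hi, ph in self._split_by_crossovers(a, b, sh, gcx):
                    new.setdefault((parent, ph), []).append((lo, hi))
        for key in new:
            new[key] = _merge_intervals(new[key])
        return new

    def trace_pair(self, ind_a: int, hap_a: int, ind_b: int, hap_b: int
                   ) -> PairSegmentSeries:
        """Segment-wise T_MRCA of two present-day haplotypes.

        Traces through the recorded pedigree; if parts of the genome have not
        coalesced by the founder generation the trace continues with fresh
        per-generation Wright-Fisher draws under the same model (the exact
        same discrete-time mechanism, sampled on the fly)."""
        A = {(int(ind_a), int(hap_a)): [(0.0, float(self.L))]}
        B = {(int(ind_b), int(hap_b)): [(0.0, float(self.L))]}
        done: list[tuple[float, float, float]] = []
        G = self.generations
        gen_back = 0
        while True:
            gen_back += 1
            if gen_back <= G:
                g = G - gen_back  # index into per-generation records
                p1, p2 = self.parent1[g], self.parent2[g]
                sh, cx = self.start_hap[g], self.crossovers[g]
            else:
                p1, p2, sh, cx = self._fresh_generation(A, B, gen_back)
            A = self._step_lineage(A, p1, p2, sh, cx)
            B = self._step_lineage(B, p1, p2, sh, cx)
            # coalescence: overlapping intervals on a shared ancestral haplotype
            for key in set(A) & set(B):
                inter = _intersect_intervals(A[key], B[key])
                if inter:
                    for a, b in inter:
                        done.append((a, b, float(gen_back)))
                    A[key] = _subtract_intervals(A[key], inter)
                    B[key] = _subtract_intervals(B[key], inter)
                    if not A[key]:
                        del A[key]
                    if not B[key]:
                        del B[key]
            remaining = sum(b - a for iv in A.values() for a, b in iv)
            if remaining <= 0 or not A or not B:
                break
        return _segments_from_pieces(done, self.L)

    def _fresh_generation(self, A, B, gen_back):
        """On-the-fly parent draws once the recorded pedigree is exhausted."""
        tbp = gen_back  # generations before present of the parent side
        epoch = self.model.epoch_at(min(tbp, 10**12))
        sigma, r = epoch.sigma, epoch.rec_rate
        n_par = self._size_at(min(tbp, 10**12))
        rng = self._rng
        inds = sorted({ind for ind, _ in A} | {ind for ind, _ in B})
        max_ind = (max(inds) + 1) if inds else 1
        p1 = np.zeros(max_ind, dtype=np.int64)
        p2 = np.zeros(max_ind, dtype=np.int64)
        sh = np.zeros(2 * max_ind, dtype=np.uint8)
        cx: dict[int, np.ndarray] = {}
        for ind in inds:
            a = int(rng.integers(0, n_par))
            if rng.random() < sigma or n_par == 1:
                b = a
            else:
                b = int(rng.integers(0, n_par - 1))
                b += b >= a
            p1[ind], p2[ind] = a, b
            for hap in (0, 1):
                gam = 2 * ind + hap
                sh[gam] = rng.integers(0, 2)
                k = rng.poisson(r * self.L)
                if k:
                    cx[gam] = np.sort(rng.uniform(0, self.L, k))
        return p1, p2, sh, cx


def _merge_intervals(ivs):
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(v) for v in out]


def _intersect_intervals(xs, ys):
    out = []
    for a, b in xs:
        for c, d in ys:
            lo, hi = max(a, c), min(b, d)
            if hi > lo:
                out.append((lo, hi))
    return _merge_intervals(out) if out else []


def _subtract_intervals(xs, ys):
    out = []
    for a, b in xs:
        pieces = [(a, b)]
        for c, d in ys:
            nxt = []
            for lo, hi in pieces:
                if d <= lo or c >= hi:
                    nxt.append((lo, hi))
                else:
                    if lo < c:
                        nxt.append((lo, c))
                    if d < hi:
                        nxt.append((d, hi))
            pieces = nxt
        out.extend(pieces)
    return out


def _segments_from_pieces(pieces, L):
    """Assemble (start, end, tmrca) pieces into an integer-bp tiling series."""
    pieces = sorted(pieces)
    starts, ends, ages = [], [], []
    for a, b, t in pieces:
        if ages and ages[-1] == t and abs(ends[-1] - a) < 1e-9:
            ends[-1] = b
        else:
            starts.append(a)
            ends.append(b)
            ages.append(t)
    # floor to integer bp, drop empties, merge equal-age neighbours
    si = np.floor(starts).astype(np.int64)
    ei = np.floor(ends).astype(np.int64)
    ei[-1] = L
    si[0] = 0
    keep = ei > si
    si, ei, ag = si[keep], ei[keep], np.array(ages)[keep]
    si[1:] = ei[:-1]
    m_s, m_e, m_a = [], [], []
    for a, b, t in zip(si, ei, ag):
        if m_a and m_a[-1] == t:
            m_e[-1] = b
        else:
            m_s.append(a)
            m_e.append(b)
            m_a.append(t)
    return PairSegmentSeries(int(L), m_s, m_e, m_a)


def simulate_wf_oracle(
    model: DemographicModel,
    n: int,
    L: int,
    mu: float,
    generations: int,
    rng: RngState,
    return_record: bool = False,
):
    """Explicit forward diploid Wright-Fisher simulation with selfing.

    Each offspring is produced by self-fertilization of a single parent with
    probability ``σ`` or by outcrossing between two distinct parents; meioses
    recombine at rate ``r`` per bp.  ``n`` haplotypes are sampled from
    distinct present-day individuals; returns the mutation overlay and the
    T_MRCA-segment series for the first sampled pair (and optionally the
    :class:`WFRecord` for tracing further pairs).

    Test-scale oracle: enforces ``N ≤ 2000``, ``L ≤ 100 kb`` and
    ``generations ≥ 10 N``.
    """
    max_N = max(int(round(e.N)) for e in model.epochs)
    if max_N > 2000:
        raise ValueError("WF oracle restricted to N <= 2000")
    if L > 100_000:
        raise ValueError("WF oracle restricted to L <= 100 kb")
    if generations < 10 * max_N:
        raise ValueError("WF oracle needs generations >= 10 N for burn-in")
    if n < 2:
        raise ValueError("need at least two haplotypes")
    g = rng.generator()
    record = WFRecord(model, L, generations, g)
    n_present = record.sizes[-1]
    inds = g.choice(n_present, size=n, replace=False)
    series = record.trace_pair(inds[0], 0, inds[1], 0)
    aln = overlay_mutations(series, mu, rng.child(1))
    if return_record:
        return aln, series, record, inds
    return aln, series
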