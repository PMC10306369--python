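"""Rejection ABC with PLS-reduced summary statistics.

Two competing demographic models are compared:

- model 1: constant population size ``N`` with a single stepwise change in
  selfing rate from ``sigma_anc`` to ``sigma_pres`` at ``t_sigma``;
- model 2: constant selfing rate ``sigma`` with a single stepwise change in
  population size from ``N_anc`` to ``N_pres`` at ``t_N``.

Reference tables pair prior draws with simulated summary vectors; parameter
posteriors come from plain rejection on Euclidean distance in the table's
PLS-score space, and model choice from joint rejection of the pooled tables
(normalized by the pooled mean/sd — per-table PLS maps are fitted against
different parameter sets and are not comparable across models).  A transition
to selfing is called when the Bayes factor exceeds ``sqrt(10)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cross_decomposition import PLSRegression

from .selfing_model import TransitionScenario, scenario_to_epochs
from .coalsim import RngState, simulate_sample, HaplotypeAlignment
from .sumstats import (
    LDBins,
    SummaryVector,
    combine_summaries,
    summary_vector,
    window_diversity,
    DEFAULT_WINDOW_SIZE,
)

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "SimDims",
    "ReferenceTable",
    "PosteriorSample",
    "ModelChoiceResult",
    "default_prior",
    "sample_prior",
    "params_to_scenario",
    "simulate_dataset",
    "summarize_dataset",
    "pilot_class_edges",
    "build_reference_table",
    "fit_pls",
    "abc_reject",
    "model_choice",
    "posterior_summary",
    "validate_performance",
    "BF_DETECTION_THRESHOLD",
]

#: Bayes-factor threshold for calling a transition to selfing
BF_DETECTION_THRESHOLD = math.sqrt(10.0)


@dataclass(frozen=True)
class ParamPrior:
    """Independent prior for one parameter: ``uniform`` or ``loguniform``."""

    kind: str
    low: float
    high: float

    def __post_init__(self):
        if self.kind not in ("uniform", "loguniform"):
            raise ValueError("prior kind must be 'uniform' or 'loguniform'")
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError("prior bounds must be finite")
        if self.low > self.high:
            raise ValueError("prior lower bound must not exceed the upper bound")
        if self.kind == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform bounds must be positive")

    def draw(self, rng: np.random.Generator, size=None):
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size)
        return 10 ** rng.uniform(np.log10(self.low), np.log10(self.high), size)

    def transform(self, x):
        """Sampling-scale transform used for PLS targets and KDE grids."""
        return np.log10(x) if self.kind == "loguniform" else np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PriorSpec:
    """Named, ordered priors for one model's free parameters."""

    model_id: int
    params: dict[str, ParamPrior]

    @property
    def names(self) -> list[str]:
        return list(self.params)


def default_prior(model_id: int) -> PriorSpec:
    """Declared default priors (overridable in configuration)."""
    if model_id == 1:
        return PriorSpec(1, {
            "N": ParamPrior("loguniform", 1e3, 1e6),
            "sigma_anc": ParamPrior("uniform", 0.0, 0.2),
            "sigma_pres": ParamPrior("uniform", 0.8, 0.999),
            "t_sigma": ParamPrior("loguniform", 1e2, 1e6),
        })
    if model_id == 2:
        return PriorSpec(2, {
            "N_pres": ParamPrior("loguniform", 1e3, 1e6),
            "N_anc": ParamPrior("loguniform", 1e3, 1e6),
            "sigma": ParamPrior("uniform", 0.0, 0.999),
            "t_N": ParamPrior("loguniform", 1e2, 1e6),
        })
    raise ValueError("model_id must be 1 or 2")


def sample_prior(spec: PriorSpec, rng: RngState, size: int | None = None):
    """Independent draws per parameter; a dict for ``size=None`` else a
    DataFrame with one row per draw."""
    g = rng.generator()
    if size is None:
        return {name: float(p.draw(g)) for name, p in spec.params.items()}
    return pd.DataFrame({name: p.draw(g, size) for name, p in spec.params.items()})


@dataclass(frozen=True)
class SimDims:
    """Dataset dimensions shared by observed and simulated data."""

    n: int = 20
    L: int = 1_000_000
    n_loci: int = 5
    mu: float = 1e-8
    r: float = 1e-8
    window_size: int = DEFAULT_WINDOW_SIZE
    spec: str = "SFS_LD_TM_WIN"
    ld_bins: LDBins = field(default_factory=LDBins)


def params_to_scenario(model_id: int, params: dict, dims: SimDims) -> TransitionScenario:
    if model_id == 1:
        return TransitionScenario(
            N_pres=params["N"], N_anc=params["N"], t_N=0.0,
            sigma_pres=params["sigma_pres"], sigma_anc=params["sigma_anc"],
            t_sigma=params["t_sigma"], rec_rate=dims.r, mut_rate=dims.mu,
        )
    if model_id == 2:
        return TransitionScenario(
            N_pres=params["N_pres"], N_anc=params["N_anc"], t_N=params["t_N"],
            sigma_pres=params["sigma"], sigma_anc=params["sigma"], t_sigma=0.0,
            rec_rate=dims.r, mut_rate=dims.mu,
        )
    raise ValueError("model_id must be 1 or 2")


def simulate_dataset(scenario: TransitionScenario, dims: SimDims, rng: RngState
                     ) -> list[HaplotypeAlignment]:
    """Independent loci simulated under one scenario."""
    model = scenario_to_epochs(scenario)
    return [
        simulate_sample(model, dims.n, dims.L, dims.mu, rng.child(k)).alignment
        for k in range(dims.n_loci)
    ]


def summarize_dataset(alns: list[HaplotypeAlignment], dims: SimDims, class_edges,
                      rng: RngState) -> SummaryVector:
    """Per-locus summaries averaged element-wise (combined statistics)."""
    vecs = [
        summary_vector(aln, dims.spec, dims.ld_bins, class_edges,
                       dims.window_size, rng.child(k))
        for k, aln in enumerate(alns)
    ]
    return combine_summaries(vecs)


def pilot_class_edges(
    prior: PriorSpec,
    dims: SimDims,
    rng: RngState,
    n_pilot: int = 1000,
    n_classes: int = 8,
) -> np.ndarray:
    """Diversity-class edges for TM_win from a prior-predictive pilot batch.

    Window counts for a sample of size two are pooled over ``n_pilot`` prior
    draws (one locus each; only a pair is simulated, which suffices for the
    pairwise window-count distribution) and the edges placed at equally
    spaced percentiles.  Edges are frozen with the reference table so that
    observed and simulated data are always classified identically.
    """
    counts = []
    for k in range(n_pilot):
        params = sample_prior(prior, rng.child(2 * k))
        scenario = params_to_scenario(prior.model_id, params, dims)
        sim = simulate_sample(scenario_to_epochs(scenario), 2, dims.L, dims.mu,
                              rng.child(2 * k + 1))
        counts.append(window_diversity(sim.alignment.pair_view(0, 1),
                                       dims.window_size).counts)
    pooled = np.concatenate(counts)
    qs = np.linspace(0, 100, n_classes + 1)[1:-1]
    edges = np.unique(np.percentile(pooled, qs))
    return edges[edges > 0] if np.any(edges > 0) else np.array([1.0])


@dataclass
class ReferenceTable:
    """Prior draws paired with simulated summary vectors for one model.

    Normalization (per-column mean/sd, zero-variance columns dropped) and the
    optional PLS map are fitted on this table's rows only and applied
    identically to any observed vector.
    """

    model_id: int
    prior: PriorSpec
    dims: SimDims
    class_edges: np.ndarray
    param_names: list[str]
    params: np.ndarray
    stat_names: list[str]
    stats: np.ndarray
    norm_mean: np.ndarray = None
    norm_sd: np.ndarray = None
    keep_cols: np.ndarray = None
    pls_center: np.ndarray | None = None
    pls_rotations: np.ndarray | None = None
    n_components: int | None = None

    @property
    def n_sims(self) -> int:
        return self.params.shape[0]

    def fit_normalizer(self) -> None:
        mean = self.stats.mean(axis=0)
        sd = self.stats.std(axis=0, ddof=0)
        self.keep_cols = sd > 0
        self.norm_mean, self.norm_sd = mean, sd

    def normalize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        keep = self.keep_cols
        return (X[:, keep] - self.norm_mean[keep]) / self.norm_sd[keep]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Distance space: PLS scores if fitted, else normalized stats."""
        Z = self.normalize(X)
        if self.pls_rotations is not None:
            Z = (Z - self.pls_center) @ self.pls_rotations
        return Z

    # -- persistence --------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.params, columns=self.param_names).to_csv(
            d / "params.tsv", sep="\t", index=False)
        pd.DataFrame(self.stats, columns=self.stat_names).to_csv(
            d / "stats.tsv", sep="\t", index=False)
        meta = {
            "model_id": self.model_id,
            "prior": {k: asdict(v) for k, v in self.prior.params.items()},
            "dims": {**{k: v for k, v in asdict(self.dims).items() if k != "ld_bins"},
                     "ld_breakpoints": list(self.dims.ld_bins.breakpoints)},
            "class_edges": self.class_edges.tolist(),
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
            "keep_cols": self.keep_cols.astype(int).tolist(),
            "pls_center": None if self.pls_center is None else self.pls_center.tolist(),
            "pls_rotations": None if self.pls_rotations is None
            else self.pls_rotations.tolist(),
            "n_components": self.n_components,
        }
        (d / "table.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "ReferenceTable":
        d = Path(directory)
        meta = json.loads((d / "table.json").read_text())
        params = pd.read_csv(d / "params.tsv", sep="\t")
        stats = pd.read_csv(d / "stats.tsv", sep="\t")
        dims_meta = dict(meta["dims"])
        bps = dims_meta.pop("ld_breakpoints")
        dims = SimDims(**dims_meta, ld_bins=LDBins(breakpoints=tuple(bps)))
        prior = PriorSpec(meta["model_id"],
                          {k: ParamPrior(**v) for k, v in meta["prior"].items()})
        table = cls(
            model_id=meta["model_id"], prior=prior, dims=dims,
            class_edges=np.array(meta["class_edges"]),
            param_names=list(params.columns), params=params.to_numpy(float),
            stat_names=list(stats.columns), stats=stats.to_numpy(float),
        )
        table.norm_mean = np.array(meta["norm_mean"])
        table.norm_sd = np.array(meta["norm_sd"])
        table.keep_cols = np.array(meta["keep_cols"], dtype=bool)
        if meta["pls_center"] is not None:
            table.pls_center = np.array(meta["pls_center"])
            table.pls_rotations = np.array(meta["pls_rotations"])
            table.n_components = meta["n_components"]
        return table


def build_reference_table(
    model_id: int,
    prior: PriorSpec,
    dims: SimDims,
    n_sims: int,
    rng: RngState,
    class_edges=None,
    n_pilot: int = 1000,
    min_sims: int = 100,
) -> ReferenceTable:
    """Simulate a reference table under one model's prior.

    If no frozen ``class_edges`` are supplied they are first derived from a
    prior-predictive pilot batch (see :func:`pilot_class_edges`).
    """
    if n_sims < min_sims:
        raise ValueError(f"reference tables need at least {min_sims} simulations")
    if prior.model_id != model_id:
        raise ValueError("prior does not belong to the requested model")
    if class_edges is None:
        class_edges = pilot_class_edges(prior, dims, rng.child(0), n_pilot=n_pilot)
    class_edges = np.asarray(class_edges, dtype=float)
    draws = sample_prior(prior, rng.child(1), size=n_sims)
    stats_rows = []
    stat_names = None
    for i in range(n_sims):
        params = draws.iloc[i].to_dict()
        scenario = params_to_scenario(model_id, params, dims)
        try:
            alns = simulate_dataset(scenario, dims, rng.child(10 + 2 * i))
            vec = summarize_dataset(alns, dims, class_edges, rng.child(11 + 2 * i))
        except Exception as err:  # attach the offending draw
            raise RuntimeError(f"simulation failed for draw {i}: {params}") from err
        if stat_names is None:
            stat_names = vec.names
        stats_rows.append(vec.values)
    table = ReferenceTable(
        model_id=model_id, prior=prior, dims=dims, class_edges=class_edges,
        param_names=list(draws.columns), params=draws.to_numpy(float),
        stat_names=list(stat_names), stats=np.vstack(stats_rows),
    )
    table.fit_normalizer()
    return table


def fit_pls(table: ReferenceTable, n_comp: int = 20) -> ReferenceTable:
    """Fit the table's PLS map: normalized stats regressed on (sampling-scale)
    parameters; the resulting transform is affine and deterministic."""
    X = table.normalize(table.stats)
    if not 1 <= n_comp <= X.shape[1]:
        raise ValueError(
            f"n_comp must be between 1 and the {X.shape[1]} retained columns")
    Y = np.column_stack([
        table.prior.params[name].transform(table.params[:, k])
        for k, name in enumerate(table.param_names)
    ])
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(X, Y)
    table.pls_center = pls._x_mean
    table.pls_rotations = pls.x_rotations_
    table.n_components = n_comp
    return table


@dataclass
class PosteriorSample:
    """Accepted parameter rows from one rejection run (uniform weights)."""

    param_names: list[str]
    values: np.ndarray
    distances: np.ndarray
    tolerance: float
    prior: PriorSpec

    def parameter(self, name: str) -> np.ndarray:
        return self.values[:, self.param_names.index(name)]

    @property
    def n_accepted(self) -> int:
        return self.values.shape[0]


def abc_reject(obs: SummaryVector, table: ReferenceTable, tolerance: float
               ) -> PosteriorSample:
    """Plain rejection: accept the ``tolerance`` fraction of table rows
    closest to the observation in the table's distance space (Euclidean on
    PLS scores when fitted, else on normalized stats); ties at the cutoff are
    broken by row order."""
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    if list(obs.names) != list(table.stat_names):
        raise ValueError("observation and table have mismatched statistics")
    Z = table.transform(table.stats)
    z_obs = table.transform(obs.values)[0]
    dist = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    n_acc = max(1, int(round(tolerance * table.n_sims)))
    order = np.argsort(dist, kind="stable")[:n_acc]
    return PosteriorSample(
        param_names=list(table.param_names),
        values=table.params[order],
        distances=dist[order],
        tolerance=tolerance,
        prior=table.prior,
    )


@dataclass
class ModelChoiceResult:
    """Joint-rejection model comparison under equal model priors."""

    p_model1: float
    bayes_factor: float
    n_accepted_m1: int
    n_accepted_m2: int
    capped: bool

    @property
    def transition_detected(self) -> bool:
        return self.bayes_factor >= BF_DETECTION_THRESHOLD


def model_choice(obs: SummaryVector, table_m1: ReferenceTable,
                 table_m2: ReferenceTable, tolerance: float) -> ModelChoiceResult:
    """Pool both tables, reject jointly, and report P(model 1 | obs) and the
    Bayes factor; a zero count in either model caps the BF at
    ``n_accepted + 1`` (flagged)."""
    if list(table_m1.stat_names) != list(table_m2.stat_names):
        raise ValueError("tables have mismatched statistics")
    if not np.array_equal(table_m1.class_edges, table_m2.class_edges):
        raise ValueError("tables were built with different class edges")
    if table_m1.dims != table_m2.dims:
        raise ValueError("tables were built with different dataset dimensions")
    if table_m1.n_sims != table_m2.n_sims:
        raise ValueError("tables must hold equally many simulations")
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    pooled = np.vstack([table_m1.stats, table_m2.stats])
    labels = np.concatenate([
        np.ones(table_m1.n_sims, dtype=int), np.full(table_m2.n_sims, 2, dtype=int)])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    keep = sd > 0
    Z = (pooled[:, keep] - mean[keep]) / sd[keep]
    z_obs = (np.asarray(obs.values)[keep] - mean[keep]) / sd[keep]
    dist = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    n_acc = max(1, int(round(tolerance * len(dist))))
    order = np.argsort(dist, kind="stable")[:n_acc]
    n1 = int((labels[order] == 1).sum())
    n2 = n_acc - n1
    p1 = n1 / n_acc
    capped = n1 == 0 or n2 == 0
    if n2 == 0:
        bf = float(n_acc + 1)
    elif n1 == 0:
        bf = 1.0 / (n_acc + 1)
    else:
        bf = n1 / n2
    return ModelChoiceResult(p_model1=p1, bayes_factor=bf,
                             n_accepted_m1=n1, n_accepted_m2=n2, capped=capped)


def posterior_summary(samples: list[PosteriorSample], parameter: str,
                      grid_size: int = 512) -> dict:
    """Mode of the averaged posterior density and 95% credibility interval.

    Per replicate, a Gaussian KDE (Scott's rule) of the accepted values is
    evaluated on a fixed grid spanning the prior support (on the parameter's
    sampling scale, i.e. log10 for log-uniform priors); densities are
    averaged across replicates and the mode is the grid argmax.  The interval
    is the 2.5/97.5% quantile range of the pooled accepted values.
    """
    if not samples:
        raise ValueError("need at least one posterior sample")
    prior = samples[0].prior.params[parameter]
    pooled = np.concatenate([s.parameter(parameter) for s in samples])
    if pooled.size == 0:
        raise ValueError("empty acceptance")
    lo, hi = prior.transform(prior.low), prior.transform(prior.high)
    grid = np.linspace(lo, hi, grid_size)
    dens = np.zeros(grid_size)
    for s in samples:
        x = prior.transform(s.parameter(parameter))
        if np.std(x) == 0:
            # degenerate cloud: point mass at the nearest grid point
            k = int(np.argmin(np.abs(grid - x[0])))
            d = np.zeros(grid_size)
            d[k] = 1.0
        else:
            d = gaussian_kde(x)(grid)
        dens += d / len(samples)
    mode_t = grid[int(np.argmax(dens))]
    mode = 10**mode_t if prior.kind == "loguniform" else float(mode_t)
    ci = (float(np.percentile(pooled, 2.5)), float(np.percentile(pooled, 97.5)))
    if np.std(pooled) == 0:
        mode = float(pooled[0])
        ci = (float(pooled[0]), float(pooled[0]))
    return {"mode": float(mode), "ci95": ci, "n_accepted": int(pooled.size)}


def validate_performance(
    t_sigma_grid,
    n_reps: int,
    dims: SimDims,
    table_m1: ReferenceTable,
    table_m2: ReferenceTable,
    rng: RngState,
    tolerance: float = 0.01,
    threshold: float = BF_DETECTION_THRESHOLD,
    true_params: dict | None = None,
) -> pd.DataFrame:
    """Model-choice and recovery performance over a grid of transition ages.

    For each ``t_sigma`` in the grid, ``n_reps`` pseudo-observed datasets are
    simulated under model 1 (defaults ``N=40,000``, ``sigma_anc=0.1``,
    ``sigma_pres=0.99``), run through model choice and rejection, and the
    fraction of datasets with ``BF >= threshold`` plus posterior quantiles
    for ``t_sigma`` are tabulated.
    """
    defaults = {"N": 40_000.0, "sigma_anc": 0.1, "sigma_pres": 0.99}
    if true_params:
        defaults.update(true_params)
    rows = []
    for gi, t_sigma in enumerate(t_sigma_grid):
        params = {**defaults, "t_sigma": float(t_sigma)}
        scenario = params_to_scenario(1, params, dims)
        detected = 0
        post_samples = []
        for rep in range(n_reps):
            sub = rng.child(1000 * gi + 2 * rep)
            alns = simulate_dataset(scenario, dims, sub)
            obs = summarize_dataset(alns, dims, table_m1.class_edges,
                                    rng.child(1000 * gi + 2 * rep + 1))
            mc = model_choice(obs, table_m1, table_m2, tolerance)
            detected += int(mc.bayes_factor >= threshold)
            post_samples.append(abc_reject(obs, table_m1, tolerance))
        pooled = np.concatenate([p.parameter("t_sigma") for p in post_samples])
        summ = posterior_summary(post_samples, "t_sigma")
        rows.append({
            "t_sigma": float(t_sigma),
            "correct_fraction": detected / n_reps,
            "post_mode": summ["mode"],
            "post_q025": float(np.percentile(pooled, 2.5)),
            "post_q50": float(np.percentile(pooled, 50)),
            "post_q975": float(np.percentile(pooled, 97.5)),
        })
    return pd.DataFrame(rows)
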