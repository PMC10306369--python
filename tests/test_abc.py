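"""Priors, PLS, rejection, model choice and posterior summaries."""

import numpy as np
import pytest
from scipy import stats

from selfkit.coalsim import RngState
from selfkit.abc import (
    ParamPrior,
    PosteriorSample,
    PriorSpec,
    ReferenceTable,
    SimDims,
    abc_reject,
    build_reference_table,
    fit_pls,
    model_choice,
    posterior_summary,
    sample_prior,
)
from selfkit.sumstats import SummaryVector


class TestSamplePrior:
    def test_degenerate_bounds_constant(self):
        spec = PriorSpec(1, {"x": ParamPrior("uniform", 5.0, 5.0)})
        draws = sample_prior(spec, RngState(1), size=100)
        assert np.all(draws["x"] == 5.0)

    def test_uniform_distribution(self):
        spec = PriorSpec(1, {"x": ParamPrior("uniform", 0.0, 1.0)})
        draws = sample_prior(spec, RngState(2), size=10_000)["x"]
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    def test_loguniform_distribution(self):
        spec = PriorSpec(1, {"x": ParamPrior("loguniform", 1e2, 1e6)})
        draws = np.log10(sample_prior(spec, RngState(3), size=10_000)["x"])
        assert stats.kstest(draws, "uniform", args=(2, 4)).pvalue > 0.01

    def test_determinism(self):
        spec = PriorSpec(1, {"x": ParamPrior("loguniform", 1.0, 10.0)})
        a = sample_prior(spec, RngState(4), size=10)
        b = sample_prior(spec, RngState(4), size=10)
        assert a.equals(b)

    @pytest.mark.parametrize("kind, lo, hi", [
        ("uniform", 1.0, 0.0), ("loguniform", -1.0, 10.0),
        ("loguniform", np.inf, np.inf), ("normal", 0.0, 1.0),
    ])
    def test_invalid_bounds(self, kind, lo, hi):
        with pytest.raises(ValueError):
            ParamPrior(kind, lo, hi)


def synthetic_table(n=400, n_stats=12, noise=0.05, seed=0):
    """Table whose stats are exact linear maps of 3 parameters plus noise."""
    rng = np.random.default_rng(seed)
    prior = PriorSpec(1, {k: ParamPrior("uniform", 0.0, 1.0) for k in "abc"})
    params = rng.uniform(0, 1, (n, 3))
    A = rng.normal(size=(3, n_stats))
    stats_ = params @ A + noise * rng.normal(size=(n, n_stats))
    table = ReferenceTable(
        model_id=1, prior=prior, dims=SimDims(), class_edges=np.array([1.0]),
        param_names=list("abc"), params=params,
        stat_names=[f"s{i}" for i in range(n_stats)], stats=stats_,
    )
    table.fit_normalizer()
    return table


class TestFitPLS:
    def test_linear_ground_truth_recovered(self):
        table = fit_pls(synthetic_table(), n_comp=3)
        scores = table.transform(table.stats)
        # regression of params on the 3 scores should explain nearly all variance
        X = np.column_stack([scores, np.ones(len(scores))])
        resid = table.params - X @ np.linalg.lstsq(X, table.params, rcond=None)[0]
        r2 = 1 - resid.var() / table.params.var()
        assert r2 > 0.95

    @pytest.mark.parametrize("n_comp", [0, 999])
    def test_component_count_validated(self, n_comp):
        with pytest.raises(ValueError):
            fit_pls(synthetic_table(), n_comp=n_comp)

    def test_transform_deterministic(self):
        table = fit_pls(synthetic_table(), n_comp=2)
        a = table.transform(table.stats)
        b = table.transform(table.stats)
        np.testing.assert_array_equal(a, b)


class TestAbcReject:
    def obs_from_row(self, table, i):
        return SummaryVector(list(table.stat_names), table.stats[i].copy(), "custom")

    def test_tolerance_one_returns_prior(self):
        table = synthetic_table()
        post = abc_reject(self.obs_from_row(table, 0), table, 1.0)
        assert post.n_accepted == table.n_sims
        for k, name in enumerate(table.param_names):
            assert stats.ks_2samp(post.parameter(name), table.params[:, k]).pvalue > 0.99

    def test_exact_row_recovered(self):
        table = synthetic_table()
        post = abc_reject(self.obs_from_row(table, 17), table, 1 / table.n_sims)
        np.testing.assert_array_equal(post.values[0], table.params[17])
        assert post.n_accepted == 1

    def test_acceptance_fraction_honored(self):
        table = synthetic_table()
        post = abc_reject(self.obs_from_row(table, 0), table, 0.25)
        assert abs(post.n_accepted - 100) <= 1

    def test_dimension_mismatch_rejected(self):
        table = synthetic_table()
        bad = SummaryVector(["x", "y"], np.zeros(2), "custom")
        with pytest.raises(ValueError):
            abc_reject(bad, table, 0.1)


def paired_tables(stats1, stats2):
    """Minimal table pair sharing dims/edges for model-choice tests."""
    def mk(model_id, stats_):
        prior = PriorSpec(model_id, {"p": ParamPrior("uniform", 0, 1)})
        t = ReferenceTable(
            model_id=model_id, prior=prior, dims=SimDims(),
            class_edges=np.array([1.0]), param_names=["p"],
            params=np.linspace(0, 1, len(stats_))[:, None],
            stat_names=["s0"], stats=np.asarray(stats_, float)[:, None],
        )
        t.fit_normalizer()
        return t
    return mk(1, stats1), mk(2, stats2)


class TestModelChoice:
    def test_balanced_acceptance_bf_one(self):
        t1, t2 = paired_tables(np.arange(0, 20, 2), np.arange(1, 21, 2))
        obs = SummaryVector(["s0"], np.array([0.0]), "custom")
        res = model_choice(obs, t1, t2, tolerance=0.5)
        assert res.bayes_factor == pytest.approx(1.0)
        assert res.p_model1 == pytest.approx(0.5)

    def test_one_sided_acceptance_capped(self):
        t1, t2 = paired_tables(np.linspace(0, 1, 10), np.linspace(100, 101, 10))
        obs = SummaryVector(["s0"], np.array([0.0]), "custom")
        res = model_choice(obs, t1, t2, tolerance=0.25)
        assert res.capped and res.n_accepted_m2 == 0
        assert res.bayes_factor == res.n_accepted_m1 + res.n_accepted_m2 + 1
        assert res.transition_detected

    def test_mismatched_tables_rejected(self):
        t1, t2 = paired_tables(np.arange(10), np.arange(10))
        t2.stat_names = ["other"]
        obs = SummaryVector(["s0"], np.array([0.0]), "custom")
        with pytest.raises(ValueError):
            model_choice(obs, t1, t2, 0.5)


class TestPosteriorSummary:
    def mk_sample(self, values, kind="uniform", lo=0.0, hi=10.0):
        prior = PriorSpec(1, {"x": ParamPrior(kind, lo, hi)})
        values = np.asarray(values, float)[:, None]
        return PosteriorSample(["x"], values, np.zeros(len(values)), 0.1, prior)

    def test_degenerate_acceptance(self):
        out = posterior_summary([self.mk_sample([3.0] * 5)], "x")
        assert out["mode"] == 3.0
        assert out["ci95"] == (3.0, 3.0)

    def test_two_cloud_mode_at_higher_peak(self):
        rng = np.random.default_rng(0)
        s1 = self.mk_sample(rng.normal(2.0, 0.1, 50))
        s2 = self.mk_sample(np.concatenate([
            rng.normal(2.0, 0.1, 40), rng.normal(8.0, 0.1, 10)]))
        out = posterior_summary([s1, s2], "x")
        assert abs(out["mode"] - 2.0) < 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary([], "x")


class TestValidatePerformance:
    def test_deterministic_output_table(self):
        from selfkit.abc import validate_performance

        dims = TestBuildReferenceTable.DIMS
        prior1 = TestBuildReferenceTable.PRIOR
        prior2 = PriorSpec(2, {
            "N_pres": ParamPrior("loguniform", 2e3, 2e4),
            "N_anc": ParamPrior("loguniform", 2e3, 2e4),
            "sigma": ParamPrior("uniform", 0.0, 0.999),
            "t_N": ParamPrior("loguniform", 1e2, 1e5),
        })
        edges = [1, 3, 6]
        t1 = fit_pls(build_reference_table(1, prior1, dims, 100, RngState(5),
                                           class_edges=edges), 5)
        t2 = build_reference_table(2, prior2, dims, 100, RngState(6),
                                   class_edges=edges)
        kw = dict(t_sigma_grid=[1_000.0, 50_000.0], n_reps=3, dims=dims,
                  table_m1=t1, table_m2=t2, tolerance=0.1,
                  true_params={"N": 8_000.0})
        a = validate_performance(rng=RngState(9), **kw)
        b = validate_performance(rng=RngState(9), **kw)
        assert a.equals(b)
        assert set(a.columns) >= {"t_sigma", "correct_fraction", "post_mode"}
        assert a["correct_fraction"].between(0, 1).all()


class TestBuildReferenceTable:
    DIMS = SimDims(n=4, L=50_000, n_loci=1, mu=1e-8, r=1e-8)
    PRIOR = PriorSpec(1, {
        "N": ParamPrior("loguniform", 2e3, 2e4),
        "sigma_anc": ParamPrior("uniform", 0.0, 0.2),
        "sigma_pres": ParamPrior("uniform", 0.8, 0.999),
        "t_sigma": ParamPrior("loguniform", 1e2, 1e5),
    })

    def test_too_few_sims_rejected(self):
        with pytest.raises(ValueError):
            build_reference_table(1, self.PRIOR, self.DIMS, 10, RngState(1))

    def test_reproducible_and_normalized(self, tmp_path):
        edges = [1, 3, 6]
        a = build_reference_table(1, self.PRIOR, self.DIMS, 100, RngState(5),
                                  class_edges=edges)
        b = build_reference_table(1, self.PRIOR, self.DIMS, 100, RngState(5),
                                  class_edges=edges)
        np.testing.assert_array_equal(a.stats, b.stats)
        Z = a.normalize(a.stats)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-10)
        # round-trip persistence preserves the transform exactly
        a = fit_pls(a, 5)
        a.save(tmp_path / "tab")
        back = ReferenceTable.load(tmp_path / "tab")
        np.testing.assert_allclose(back.transform(a.stats), a.transform(a.stats))
        assert back.prior.params["N"].kind == "loguniform"
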