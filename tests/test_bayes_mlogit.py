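"""Design matrices, the log posterior, MCMC behaviour and diagnostics."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import maihda as m
from maihda.bayes_mlogit import split_rhat, trace_data
from maihda.synthetic_data import SyntheticConfig, SyntheticVariable, generate


def small_dataset(seed=0, n=400, sigma2=0.2, betas=None, beta0=-0.5):
    variables = (
        SyntheticVariable("a", ("ref", "alt")),
        SyntheticVariable("b", ("x", "y", "z")),
    )
    if betas is None:
        betas = {("a", "alt"): 0.6, ("b", "y"): -0.4, ("b", "z"): 0.3}
    cfg = SyntheticConfig(
        n_records=n, variables=variables, beta0=beta0,
        betas=betas, sigma2_u=sigma2, seed=seed,
    )
    dataset, truth = generate(cfg)
    index = m.build_strata(dataset, ["a", "b"])
    return dataset, truth, index


class TestBuildDesign:
    def test_four_level_variable_gives_three_columns(self, cough_dataset):
        dataset, _ = cough_dataset
        index = m.build_strata(dataset, ["division"])
        X, names = m.build_design(
            dataset, m.ModelSpec("cough", index, fixed_vars=("division",))
        )
        assert X.shape[1] == 3
        assert names == [
            "division:Khulna", "division:Rajshahi", "division:Other divisions",
        ]

    def test_null_model_has_empty_design(self, cough_dataset):
        dataset, _ = cough_dataset
        index = m.build_strata(dataset, ["division"])
        X, names = m.build_design(dataset, m.ModelSpec("cough", index))
        assert X.shape == (dataset.n_records, 0) and names == []

    def test_all_reference_record_has_zero_row(self):
        dataset, _, index = small_dataset()
        X, _ = m.build_design(
            dataset, m.ModelSpec("outcome", index, fixed_vars=("a", "b"))
        )
        ref_rows = (dataset.records["a"] == "ref") & (dataset.records["b"] == "x")
        assert (X[ref_rows.to_numpy()] == 0).all()

    def test_unobserved_reference_fatal(self):
        dataset, _, index = small_dataset()
        dataset.records.loc[dataset.records["a"] == "ref", "a"] = "alt"
        with pytest.raises(ValueError, match="reference level"):
            m.build_design(
                dataset, m.ModelSpec("outcome", index, fixed_vars=("a",))
            )

    def test_fixed_vars_must_define_strata(self):
        dataset, _, index = small_dataset()
        with pytest.raises(ValueError, match="strata-defining"):
            m.ModelSpec("outcome", index, fixed_vars=("unknown",))


class TestLogPosterior:
    def test_matches_independent_term_by_term_recomputation(self):
        dataset, _, index = small_dataset(n=80)
        y = dataset.outcome01("outcome").to_numpy(dtype=float)
        X, _ = m.build_design(
            dataset, m.ModelSpec("outcome", index, fixed_vars=("a", "b"))
        )
        s = index.zero_based()
        J = index.observed_count
        priors = m.PriorSpec()
        rng = np.random.default_rng(1)
        for _ in range(5):
            beta0 = rng.normal()
            beta = rng.normal(size=X.shape[1])
            u = rng.normal(size=J)
            sigma2 = rng.uniform(0.05, 2.0)
            eta = beta0 + X @ beta + u[s]
            oracle = (
                stats.bernoulli.logpmf(y.astype(int), expit(eta)).sum()
                + stats.norm.logpdf(u, 0, np.sqrt(sigma2)).sum()
                + stats.norm.logpdf(beta0, 0, priors.fixed_effect_scale)
                + stats.norm.logpdf(beta, 0, priors.fixed_effect_scale).sum()
                + np.log(2)
                + stats.t.logpdf(
                    np.sqrt(sigma2), priors.stratum_sd_df,
                    scale=priors.stratum_sd_scale,
                )
            )
            ours = m.log_posterior(y, X, s, beta0, beta, u, sigma2, priors)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_nonpositive_variance_excluded(self):
        dataset, _, index = small_dataset(n=40)
        y = dataset.outcome01("outcome").to_numpy(dtype=float)
        X = np.zeros((len(y), 0))
        s = index.zero_based()
        u = np.zeros(index.observed_count)
        assert m.log_posterior(y, X, s, 0.0, np.zeros(0), u, 0.0) == -np.inf


class TestFit:
    def test_seeded_determinism(self):
        dataset, _, index = small_dataset(n=200)
        cfg = m.SamplerConfig(chains=2, iterations=300, burn_in=100, seed=9)
        spec = m.ModelSpec("outcome", index)
        f1 = m.fit(dataset, spec, config=cfg)
        f2 = m.fit(dataset, spec, config=cfg)
        for name in ("beta0", "beta", "sigma2", "u"):
            assert np.array_equal(getattr(f1, name), getattr(f2, name))
        f3 = m.fit(dataset, spec, config=m.SamplerConfig(
            chains=2, iterations=300, burn_in=100, seed=10))
        assert not np.array_equal(f1.beta0, f3.beta0)

    def test_single_class_outcome_fatal(self):
        dataset, _, index = small_dataset(n=100)
        spec0 = dataset.codebook["outcome"]
        dataset.records["outcome"] = spec0.levels[0]
        with pytest.raises(ValueError, match="single class"):
            m.fit(dataset, m.ModelSpec("outcome", index))

    def test_symmetric_null_intercept_near_zero(self):
        """With no effects and a 50% outcome, the intercept posterior sits
        at zero. Enough strata are used that the intercept is cleanly
        separated from the stratum-effect mean."""
        variables = (
            SyntheticVariable("a", tuple(f"a{i}" for i in range(4))),
            SyntheticVariable("b", tuple(f"b{i}" for i in range(8))),
        )
        dataset, _ = generate(SyntheticConfig(
            n_records=5000, variables=variables, beta0=0.0, sigma2_u=0.0, seed=3,
        ))
        index = m.build_strata(dataset, ["a", "b"])
        f = m.fit(
            dataset, m.ModelSpec("outcome", index),
            config=m.SamplerConfig(chains=2, iterations=1200, burn_in=400, seed=2),
        )
        assert abs(f.pooled("beta0").mean()) < 0.1

    def test_large_n_matches_ml_logistic(self):
        """With sigma2_u = 0 the posterior means of beta agree with an
        independent maximum-likelihood logistic fit."""
        import statsmodels.api as sm

        dataset, truth, index = small_dataset(seed=11, n=10_000, sigma2=0.0)
        spec = m.ModelSpec("outcome", index, fixed_vars=("a", "b"))
        f = m.fit(
            dataset, spec,
            config=m.SamplerConfig(chains=2, iterations=1500, burn_in=500, seed=4),
        )
        X, _ = m.build_design(dataset, spec)
        y = dataset.outcome01("outcome").to_numpy(dtype=float)
        ml = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert f.pooled("beta0").mean() == pytest.approx(ml.params[0], abs=0.1)
        for k in range(X.shape[1]):
            assert f.pooled("beta")[:, k].mean() == pytest.approx(
                ml.params[k + 1], abs=0.1
            )

    def test_prior_scale_insensitivity(self):
        """Doubling the weakly informative fixed-effect scale barely moves
        the intercept posterior."""
        dataset, _, index = small_dataset(seed=5, n=5000, sigma2=0.1)
        spec = m.ModelSpec("outcome", index)
        cfg = m.SamplerConfig(chains=2, iterations=1500, burn_in=500, seed=8)
        f_a = m.fit(dataset, spec, priors=m.PriorSpec(fixed_effect_scale=10), config=cfg)
        f_b = m.fit(dataset, spec, priors=m.PriorSpec(fixed_effect_scale=20), config=cfg)
        assert abs(f_a.pooled("beta0").mean() - f_b.pooled("beta0").mean()) < 0.02

    def test_summaries_interval_ordering(self, small_fit_pair):
        _, _, _, fit1, fit2 = small_fit_pair
        for f in (fit1, fit2):
            summ = f.summaries()
            assert (summ["ci_lower"] <= summ["median"]).all()
            assert (summ["median"] <= summ["ci_upper"]).all()
            assert (f.pooled("sigma2") > 0).all()
            assert f.u.shape[2] == f.spec.strata.observed_count


class TestOddsRatios:
    def test_zero_draws_give_unit_or(self, fake_fit_factory):
        f = fake_fit_factory(np.zeros((2, 50)))
        table = m.odds_ratios(f, force=True)
        row = table.iloc[0]
        assert (row["odds_ratio"], row["ci_lower"], row["ci_upper"]) == (1, 1, 1)
        assert not row["significant"]

    def test_lognormal_draws_near_two_and_significant(self, fake_fit_factory):
        rng = np.random.default_rng(0)
        draws = rng.normal(np.log(2), 0.01, size=(2, 2000))
        f = fake_fit_factory(
            np.zeros((2, 2000)), beta_draws=draws[..., None],
            design_columns=["a:alt"],
        )
        table = m.odds_ratios(f, force=True).set_index("parameter")
        row = table.loc["a:alt"]
        assert row["odds_ratio"] == pytest.approx(2.0, rel=0.01)
        # quantile oracle on the draw array itself
        assert row["ci_lower"] == pytest.approx(
            np.exp(np.percentile(draws, 2.5)), rel=1e-9
        )
        assert row["significant"]

    def test_unconverged_fit_refused(self, fake_fit_factory):
        chains = np.vstack([np.full(100, -1.0), np.full(100, 1.0)])
        chains = chains + np.linspace(0, 0.01, 100)  # non-constant halves
        f = fake_fit_factory(chains)
        with pytest.raises(RuntimeError, match="not converged"):
            m.odds_ratios(f)


class TestDiagnostics:
    def test_identical_constant_chains_rhat_exactly_one(self, fake_fit_factory):
        f = fake_fit_factory(np.full((2, 100), 1.234))
        diag = m.diagnostics(f).set_index("parameter")
        assert diag.loc["beta0", "rhat"] == 1.0

    def test_stationary_chains_rhat_below_1_01(self, fake_fit_factory):
        rng = np.random.default_rng(3)
        f = fake_fit_factory(rng.normal(size=(2, 10_000)))
        diag = m.diagnostics(f).set_index("parameter")
        assert diag.loc["beta0", "rhat"] < 1.01

    def test_separated_chains_fail_convergence(self, fake_fit_factory):
        rng = np.random.default_rng(4)
        draws = rng.normal(size=(2, 500)) * 0.1 + np.array([[-1.0], [1.0]])
        f = fake_fit_factory(draws)
        diag = m.diagnostics(f)
        by = diag.set_index("parameter")
        assert by.loc["beta0", "rhat"] > 1.05
        assert diag.attrs["converged"] is False

    def test_single_chain_flagged(self, fake_fit_factory):
        f = fake_fit_factory(np.random.default_rng(5).normal(size=(1, 200)))
        diag = m.diagnostics(f)
        assert "insufficient chains" in diag.attrs["note"]
        assert np.isnan(diag["rhat"]).all()

    def test_split_rhat_close_to_arviz_rank_version(self):
        import arviz as az

        rng = np.random.default_rng(6)
        draws = rng.normal(size=(4, 2000))
        ours = split_rhat(draws)
        theirs = az.rhat(draws)
        theirs = float(next(iter(theirs.data_vars.values())).values) \
            if hasattr(theirs, "data_vars") else float(theirs)
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_trace_data_long_format(self, small_fit_pair):
        _, _, _, fit1, _ = small_fit_pair
        trace = trace_data(fit1)
        assert set(trace.columns) == {"parameter", "chain", "iteration", "value"}
        n_kept = fit1.beta0.shape[1]
        assert (trace["parameter"] == "beta0").sum() == 2 * n_kept
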