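import math

import numpy as np
import pandas as pd
import pytest

from cupnest import bpmm, synthetic
from cupnest.errors import ConvergenceError, DesignError, TraitError


def _simple_spec(standardize=True):
    return bpmm.ModelSpec(response="response",
                          fixed_terms={"x1": "continuous", "x2": "continuous"},
                          standardize=standardize)


class TestBuildDesign:
    def test_incidence_bookkeeping(self):
        sc = synthetic.SyntheticScenario(n_species=3, records_per_species_fixed=2,
                                         beta_true={"x1": 1.0, "x2": 0.0},
                                         source_offset=0.0, seed=1)
        tree = synthetic.simulate_tree(sc)
        data, _ = synthetic.simulate_traits(tree, sc)
        design = bpmm.build_design(data, _simple_spec(), tree)
        assert design.Z.shape == (6, 3)
        assert np.allclose(design.Z.sum(axis=0), 2.0)
        assert np.allclose(design.Z.sum(axis=1), 1.0)
        assert np.allclose(np.diag(design.A), 1.0)

    def test_standardization_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        v = (v - v.mean()) / v.std()
        data = pd.DataFrame({"species_id": [f"s{i+1}" for i in range(40)],
                             "response": rng.normal(size=40), "x1": v,
                             "x2": rng.normal(size=40)})
        tree = synthetic.simulate_tree(synthetic.SyntheticScenario(n_species=40), seed=2)
        design = bpmm.build_design(data, _simple_spec(), tree)
        assert np.allclose(design.X[:, 1], v, atol=1e-12)

    def test_two_point_log_standardization(self):
        """log{e, e^2} standardizes to {-0.707, +0.707} with population SD."""
        data = pd.DataFrame({"species_id": ["s1", "s2", "s3", "s4"],
                             "response": [1.0, 2.0, 1.5, 2.5],
                             "vol": [math.e, math.e ** 2, math.e, math.e ** 2]})
        spec = bpmm.ModelSpec(response="response", fixed_terms={"vol": "continuous"},
                              transform_map={"vol": "log"})
        tree = synthetic.simulate_tree(synthetic.SyntheticScenario(n_species=4), seed=3)
        design = bpmm.build_design(data, spec, tree)
        assert np.allclose(sorted(set(np.round(design.X[:, 1], 6))),
                           [-1.0, 1.0])  # two-point population-SD z-scores
        assert design.X[0, 1] == pytest.approx(-1.0)

    def test_species_missing_from_tree_listed(self):
        tree = synthetic.simulate_tree(synthetic.SyntheticScenario(n_species=5), seed=4)
        data = pd.DataFrame({"species_id": ["s1", "nope"], "response": [1.0, 2.0],
                             "x1": [0.1, 0.2], "x2": [1.0, 0.0]})
        with pytest.raises(DesignError, match="nope"):
            bpmm.build_design(data, _simple_spec(), tree)

    def test_constant_predictor_rejected(self):
        tree = synthetic.simulate_tree(synthetic.SyntheticScenario(n_species=4), seed=5)
        data = pd.DataFrame({"species_id": ["s1", "s2", "s3", "s4"],
                             "response": [1, 2, 3, 4.0], "x1": [1.0] * 4,
                             "x2": [0.0, 1.0, 0.5, 0.2]})
        with pytest.raises(DesignError, match="x1"):
            bpmm.build_design(data, _simple_spec(), tree)


class TestGibbs:
    def test_seeded_runs_identical(self):
        sc = synthetic.SyntheticScenario(n_species=20, records_per_species_fixed=2,
                                         beta_true={"x1": 0.5, "x2": 0.0},
                                         source_offset=0.0, seed=6)
        tree = synthetic.simulate_tree(sc)
        data, _ = synthetic.simulate_traits(tree, sc)
        design = bpmm.build_design(data, _simple_spec(False), tree)
        settings = bpmm.MCMCSettings(n_iterations=200, burn_in=50, thin=1, seed=0)
        a = bpmm.gibbs_run(design, bpmm.PriorSpec(), settings, seed=123)
        b = bpmm.gibbs_run(design, bpmm.PriorSpec(), settings, seed=123)
        assert np.array_equal(a.beta_draws, b.beta_draws)
        assert np.array_equal(a.var_residual_draws, b.var_residual_draws)

    def test_recovery_within_three_posterior_sd(self, recovery_fit):
        """Posterior means of beta and all variance components land within
        3 posterior SDs of the generating values."""
        s = recovery_fit["sample"]
        truth = {"x1": 1.0, "x2": -0.5}
        for name, b in truth.items():
            d = s.parameter(name)
            assert abs(d.mean() - b) < 3 * d.std()
        for name, v in [("var_phylo", 0.5), ("var_species", 0.2),
                        ("var_residual", 0.3)]:
            d = s.parameter(name)
            assert abs(d.mean() - v) < 3 * d.std()

    def test_ols_limit_with_no_random_variance(self):
        """With zero phylogenetic and species variance the posterior mean of
        beta approaches the OLS estimate."""
        sc = synthetic.SyntheticScenario(
            n_species=100, records_per_species_fixed=1, sigma2_phylo=0.0,
            sigma2_species=0.0, sigma2_residual=0.3,
            beta_true={"x1": 1.0, "x2": -0.5}, source_offset=0.0, seed=8)
        tree = synthetic.simulate_tree(sc)
        data, _ = synthetic.simulate_traits(tree, sc)
        design = bpmm.build_design(data, _simple_spec(False), tree)
        settings = bpmm.MCMCSettings(n_iterations=1500, burn_in=300, thin=1, seed=0)
        sample = bpmm.gibbs_run(design, bpmm.PriorSpec(), settings, seed=21)
        coef, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        resid = design.y - design.X @ coef
        sigma2 = resid @ resid / (len(design.y) - design.X.shape[1])
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(design.X.T @ design.X)))
        post_mean = sample.beta_draws.mean(axis=0)
        assert np.all(np.abs(post_mean - coef) < 2 * se)

    def test_zero_retained_draws_rejected(self):
        sc = synthetic.SyntheticScenario(n_species=10, records_per_species_fixed=1,
                                         beta_true={"x1": 0.5, "x2": 0.0},
                                         source_offset=0.0, seed=9)
        tree = synthetic.simulate_tree(sc)
        data, _ = synthetic.simulate_traits(tree, sc)
        design = bpmm.build_design(data, _simple_spec(False), tree)
        settings = bpmm.MCMCSettings(n_iterations=100, burn_in=50, thin=200)
        with pytest.raises(ConvergenceError):
            bpmm.gibbs_run(design, bpmm.PriorSpec(), settings)


class TestMultiTree:
    def test_pooled_draw_arithmetic(self):
        sc = synthetic.SyntheticScenario(n_species=15, records_per_species_fixed=2,
                                         beta_true={"x1": 0.5, "x2": 0.0},
                                         source_offset=0.0, seed=10)
        data, _ = synthetic.simulate_traits(synthetic.simulate_tree(sc), sc)
        trees = [synthetic.simulate_tree(sc, seed=s) for s in range(25)]
        settings = bpmm.MCMCSettings(n_iterations=300, burn_in=100, thin=100,
                                     n_chains=1, seed=1, trees_per_run=25)
        assert settings.retained_per_chain == 2
        pooled = bpmm.multi_tree_run(data, _simple_spec(False), bpmm.PriorSpec(),
                                     settings, trees)
        assert pooled.n_draws == 50
        assert sorted(set(pooled.tree_index)) == list(range(25))

    def test_single_tree_equals_chain_one(self):
        sc = synthetic.SyntheticScenario(n_species=15, records_per_species_fixed=2,
                                         beta_true={"x1": 0.5, "x2": 0.0},
                                         source_offset=0.0, seed=11)
        tree = synthetic.simulate_tree(sc)
        data, _ = synthetic.simulate_traits(tree, sc)
        settings = bpmm.MCMCSettings(n_iterations=400, burn_in=100, thin=10,
                                     n_chains=1, seed=5, trees_per_run=1)
        pooled = bpmm.multi_tree_run(data, _simple_spec(False), bpmm.PriorSpec(),
                                     settings, [tree])
        design = bpmm.build_design(data, _simple_spec(False), tree)
        seed = int(np.random.SeedSequence(5).spawn(1)[0].generate_state(1)[0] % 2 ** 31)
        single = bpmm.gibbs_run(design, bpmm.PriorSpec(), settings, seed=seed)
        assert np.array_equal(pooled.beta_draws, single.beta_draws)


class TestPMCMC:
    @pytest.mark.parametrize("draws,expected", [
        ([-1, 2, 3, 4], 0.5),
        ([-2, -1, 1, 2], 1.0),
    ])
    def test_sign_counting(self, draws, expected):
        assert bpmm.pmcmc(np.array(draws, dtype=float)) == pytest.approx(expected)

    def test_floor_at_two_over_n(self):
        assert bpmm.pmcmc(np.abs(np.random.default_rng(0).normal(size=1000)) + 0.1) \
            == pytest.approx(0.002)


class TestConditionalR2:
    @staticmethod
    def _sample(beta, vp, vs, ve, n=100):
        return bpmm.PosteriorSample(
            beta_draws=np.tile(beta, (n, 1)),
            var_phylo_draws=np.full(n, vp),
            var_species_draws=np.full(n, vs),
            var_residual_draws=np.full(n, ve),
            fixed_names=["(Intercept)"], tree_index=np.zeros(n, dtype=int))

    def test_intercept_only_closed_form(self):
        # V_fix = 0 and equal components: R2 = 2/3
        s = self._sample(np.array([1.0]), 0.5, 0.5, 0.5)
        X = np.ones((10, 1))
        assert bpmm.conditional_r2(s, X) == pytest.approx(2.0 / 3.0)

    def test_vanishing_residual_limit(self):
        s = self._sample(np.array([1.0]), 0.5, 0.5, 1e-12)
        assert bpmm.conditional_r2(s, np.ones((10, 1))) == pytest.approx(1.0, abs=1e-9)

    def test_recovery_scenario_matches_plug_in(self, recovery_fit):
        """Conditional R2 from the fitted sample is close to the generative
        value computed from the known beta and predictor covariance."""
        design = recovery_fit["sample"]
        X = recovery_fit["design"].X
        v_fix = (X @ np.array([0.0, 1.0, -0.5])).var()
        expected = (v_fix + 0.7) / (v_fix + 0.7 + 0.3)
        got = bpmm.conditional_r2(recovery_fit["sample"], X)
        assert got == pytest.approx(expected, abs=0.05)


class TestPSRF:
    def test_identical_chains(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=500)
        n = len(c)
        assert bpmm.psrf([c, c]) == pytest.approx(math.sqrt((n - 1) / n), abs=1e-12)

    def test_shifted_chains_exceed_threshold(self):
        rng = np.random.default_rng(2)
        c1 = rng.normal(0, 1, 500)
        c2 = rng.normal(10, 1, 500)
        assert bpmm.psrf([c1, c2]) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(TraitError):
            bpmm.psrf([np.zeros(100)])

    def test_converged_sampler_chains(self, recovery_fit):
        """Two independently seeded chains of the recovery model converge."""
        design = recovery_fit["design"]
        settings = bpmm.MCMCSettings(n_iterations=800, burn_in=300, thin=1, seed=0)
        a = bpmm.gibbs_run(design, bpmm.PriorSpec(), settings, seed=1)
        b = bpmm.gibbs_run(design, bpmm.PriorSpec(), settings, seed=2)
        for name in ["x1", "x2", "var_residual"]:
            assert bpmm.psrf([a.parameter(name), b.parameter(name)]) < 1.1


class TestESS:
    def test_white_noise(self):
        x = np.random.default_rng(3).normal(size=2000)
        ess, _ = bpmm.ess_and_autocorr(x)
        assert abs(ess - 2000) / 2000 < 0.10

    def test_ar1_closed_form(self):
        # rho = 0.5: 1 + 2*sum(rho^k) = 3, so ESS ~ N/3
        rng = np.random.default_rng(4)
        n = 20000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * math.sqrt(1 - 0.25)
        for i in range(1, n):
            x[i] = 0.5 * x[i - 1] + eps[i]
        ess, rhos = bpmm.ess_and_autocorr(x)
        assert abs(ess - n / 3) / (n / 3) < 0.15
        assert rhos[0] == pytest.approx(0.5, abs=0.05)

    def test_negative_autocorrelation_ess_at_least_n(self):
        n = 1000
        x = np.where(np.arange(n) % 2 == 0, 1.0, -1.0) \
            + np.random.default_rng(5).normal(0, 1e-3, n)
        ess, _ = bpmm.ess_and_autocorr(x)
        assert ess >= n

    def test_zero_variance_rejected(self):
        with pytest.raises(TraitError):
            bpmm.ess_and_autocorr(np.ones(100))


class TestRepeatability:
    def test_identical_duplicates_give_one(self):
        df = pd.DataFrame({"species_id": ["a", "a", "b", "b", "c", "c"],
                           "vol": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]})
        assert bpmm.repeatability(df, "vol").repeatability == pytest.approx(1.0)

    def test_identical_species_means_give_zero(self):
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 1, 6)
        df = pd.DataFrame({"species_id": ["a", "a", "b", "b", "c", "c"],
                           "vol": noise - np.repeat(
                               [noise[:2].mean(), noise[2:4].mean(), noise[4:].mean()], 2)})
        assert bpmm.repeatability(df, "vol").repeatability == pytest.approx(0.0, abs=1e-10)

    def test_generative_oracle(self):
        """sigma2_species=4, sigma2_res=1 over 100 species x 3 records gives
        R near 0.8."""
        rng = np.random.default_rng(7)
        sp = np.repeat([f"s{i}" for i in range(100)], 3)
        mu = np.repeat(rng.normal(0, 2.0, 100), 3)
        df = pd.DataFrame({"species_id": sp, "vol": mu + rng.normal(0, 1.0, 300)})
        res = bpmm.repeatability(df, "vol")
        assert res.repeatability == pytest.approx(0.8, abs=0.05)
        assert res.n_records == 300 and res.n_species == 100

    def test_no_replication_rejected(self):
        df = pd.DataFrame({"species_id": ["a", "b", "c"], "vol": [1.0, 2.0, 3.0]})
        with pytest.raises(TraitError):
            bpmm.repeatability(df, "vol")


class TestVIF:
    def test_orthogonal_predictors(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        assert np.allclose(bpmm.vif(X), 1.0)

    def test_known_correlation_closed_form(self):
        # exact sample correlation 0.6 -> VIF = 1/(1-0.36) = 1.5625
        n = 40
        rng = np.random.default_rng(8)
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)   # orthogonalize
        z2 /= z2.std()
        x2 = 0.6 * z1 + math.sqrt(1 - 0.36) * z2
        out = bpmm.vif(pd.DataFrame({"a": z1, "b": x2}))
        assert out["a"] == pytest.approx(1.5625, abs=1e-9)
        assert out["b"] == pytest.approx(1.5625, abs=1e-9)

    def test_duplicate_predictor_rejected(self):
        x = np.random.default_rng(9).normal(size=30)
        with pytest.raises(DesignError, match="collinear"):
            bpmm.vif(pd.DataFrame({"a": x, "b": x}))


class TestSummarize:
    def test_summary_fields(self, recovery_fit):
        s = bpmm.summarize(recovery_fit["sample"], recovery_fit["design"].X)
        assert set(s.fixed.columns) == {"posterior_mean", "hpd_lower",
                                        "hpd_upper", "pmcmc"}
        assert s.fixed.loc["x1", "hpd_lower"] < 1.0 < s.fixed.loc["x1", "hpd_upper"]
        assert s.fixed.loc["x1", "pmcmc"] == pytest.approx(
            2.0 / recovery_fit["sample"].n_draws)
        assert 0 < s.conditional_r2 < 1
        assert s.variance.loc["var_phylo", "posterior_mean"] > 0

    def test_hpd_contains_central_mass(self):
        x = np.random.default_rng(10).normal(size=5000)
        lo, hi = bpmm.hpd_interval(x, 0.95)
        frac = np.mean((x >= lo) & (x <= hi))
        assert 0.945 <= frac <= 0.96
        assert lo == pytest.approx(-1.96, abs=0.15)
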