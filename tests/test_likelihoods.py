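import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import statsmodels.api as sm
from statsmodels.discrete.truncated_model import (
    TruncatedLFNegativeBinomialP,
    TruncatedLFPoisson,
)

from blockcount.likelihoods import (
    ModelParams,
    ModelSpec,
    aic,
    fit,
    hurdle_logpmf,
    marginal_loglik,
    nb_logpmf,
    poisson_logpmf,
    predict_expected_counts,
    truncated_logpmf,
    variance_inflation,
)
from conftest import make_table


# ---------------------------------------------------------------------------
# pmf primitives
# ---------------------------------------------------------------------------


class TestPmfs:
    def test_poisson_zero_at_unit_mean(self):
        assert poisson_logpmf(0, 1.0) == pytest.approx(-1.0)

    def test_nb_closed_form_kappa_one(self):
        # y=0, mu=2, kappa=1: (1/(1+2))^1 = 1/3
        assert nb_logpmf(0, 2.0, 1.0) == pytest.approx(np.log(1.0 / 3.0), abs=1e-12)

    def test_nb_poisson_limit_small_kappa(self):
        y = np.arange(51)
        diff = nb_logpmf(y, 1.7, 1e-8) - poisson_logpmf(y, 1.7)
        assert np.max(np.abs(diff)) < 1e-6

    @pytest.mark.parametrize("mu,kappa", [(3.0, 1.5), (0.3, 0.2), (8.0, 2.5)])
    def test_nb_normalizes(self, mu, kappa):
        y = np.arange(501)
        assert np.sum(np.exp(nb_logpmf(y, mu, kappa))) == pytest.approx(1.0, abs=1e-8)

    @given(
        mu=st.floats(min_value=0.05, max_value=10.0),
        kappa=st.floats(min_value=0.0, max_value=3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_nb_normalizes_property(self, mu, kappa):
        y = np.arange(801)
        assert np.sum(np.exp(nb_logpmf(y, mu, kappa))) == pytest.approx(1.0, abs=1e-8)

    def test_nb_rejects_negative_count(self):
        with pytest.raises(ValueError):
            nb_logpmf(-1, 1.0, 1.0)

    def test_truncated_poisson_closed_form(self):
        mu = np.log(2.0)
        # e^{-mu} mu / (1 - e^{-mu}) = (1/2) mu / (1/2) = mu
        assert np.exp(truncated_logpmf(1, mu)) == pytest.approx(mu, abs=1e-12)

    def test_truncated_poisson_tiny_mean_collapses_to_one(self):
        assert np.exp(truncated_logpmf(1, 1e-8)) == pytest.approx(1.0, abs=1e-6)
        assert np.isfinite(truncated_logpmf(1, 1e-12))

    @pytest.mark.parametrize("kappa", [None, 1.0, 0.4])
    def test_truncated_normalizes(self, kappa):
        y = np.arange(1, 501)
        total = np.sum(np.exp(truncated_logpmf(y, 2.0, kappa)))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_truncated_rejects_zero(self):
        with pytest.raises(ValueError):
            truncated_logpmf(0, 1.0)

    def test_hurdle_zero_mass_is_p0(self):
        assert hurdle_logpmf(0, 0.37, 2.0) == pytest.approx(np.log(0.37), abs=1e-12)

    def test_hurdle_normalizes(self):
        y = np.arange(501)
        total = np.sum(np.exp(hurdle_logpmf(y, 0.5, 2.0)))
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("kappa", [None, 0.8])
    def test_hurdle_with_matched_p0_equals_base(self, kappa):
        # p0 set to the base pmf's own zero mass reproduces the base pmf
        mu = 1.7
        p0 = np.exp(
            poisson_logpmf(0, mu) if kappa is None else nb_logpmf(0, mu, kappa)
        )
        y = np.arange(30)
        base = poisson_logpmf(y, mu) if kappa is None else nb_logpmf(y, mu, kappa)
        np.testing.assert_allclose(hurdle_logpmf(y, p0, mu, kappa), base, atol=1e-10)


class TestAicAndInflation:
    @pytest.mark.parametrize(
        "minus2, p, expected",
        [(2800.5, 5, 2810.5), (2574.9, 6, 2586.9), (2760.0, 10, 2780.0), (2671.9, 11, 2693.9)],
    )
    def test_aic_identity(self, minus2, p, expected):
        assert aic(-minus2 / 2.0, p) == pytest.approx(expected, abs=1e-12)

    def test_aic_degenerate(self):
        assert aic(0.0, 0) == 0.0

    def test_inflation_linear_variance(self):
        assert variance_inflation(1.1424, 3.0, r=1) == pytest.approx(2.1424, abs=1e-12)
        assert variance_inflation(1.1424, 0.1, r=1) == pytest.approx(2.1424, abs=1e-12)

    def test_inflation_poisson(self):
        assert variance_inflation(0.0, 5.0, r=2) == 1.0

    def test_inflation_quadratic(self):
        assert variance_inflation(2.0, 3.0, r=2) == pytest.approx(7.0)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


class TestMarginalLoglik:
    def test_sigma2_zero_equals_fixed_effects(self, small_table):
        spec_fe = ModelSpec(family="poisson", random_effects=False)
        spec_re = ModelSpec(family="poisson", random_effects=True)
        p = ModelParams(beta=np.array([-3.5, 0.001, -0.2, 0.1]), sigma2=0.0)
        assert marginal_loglik(spec_re, p, small_table) == pytest.approx(
            marginal_loglik(spec_fe, p, small_table), abs=1e-10
        )

    def test_single_block_zero_count_matches_monte_carlo(self):
        # P(y=0) = E_gamma[exp(-N e^{x'b + gamma})]
        table = make_table([0], [4], x1=[1920.0], x2=[4.1], x3=[5.0])
        beta = np.array([-3.0, 0.0005, -0.3, 0.08])
        sigma2 = 0.8
        spec = ModelSpec(family="poisson", random_effects=True, quadrature_points=25)
        ll = marginal_loglik(spec, ModelParams(beta=beta, sigma2=sigma2), table)
        rng = np.random.default_rng(7)
        gam = rng.normal(0.0, np.sqrt(sigma2), 10**6)
        x = np.array([1.0, 1920.0, 4.1, 5.0])
        draws = np.exp(-4.0 * np.exp(x @ beta + gam))
        mc, mc_se = draws.mean(), draws.std() / 1000.0
        assert abs(np.exp(ll) - mc) < 3 * mc_se

    def test_single_block_positive_count_matches_monte_carlo(self):
        table = make_table([3], [9], x1=[1925.0], x2=[3.9], x3=[5.3])
        beta = np.array([-3.0, 0.0005, -0.3, 0.08])
        sigma2 = 0.5
        spec = ModelSpec(family="nb", random_effects=True, quadrature_points=25)
        ll = marginal_loglik(
            spec, ModelParams(beta=beta, kappa=0.7, sigma2=sigma2), table
        )
        rng = np.random.default_rng(11)
        gam = rng.normal(0.0, np.sqrt(sigma2), 10**6)
        x = np.array([1.0, 1925.0, 3.9, 5.3])
        mu = 9.0 * np.exp(x @ beta + gam)
        draws = np.exp(nb_logpmf(3, mu, 0.7))
        mc, mc_se = draws.mean(), draws.std() / 1000.0
        assert abs(np.exp(ll) - mc) < 3 * mc_se

    def test_quadrature_converges_on_fixture(self, small_table):
        p = ModelParams(beta=np.array([-3.5, 0.001, -0.2, 0.1]), sigma2=0.6)
        lls = {
            q: marginal_loglik(
                ModelSpec(family="poisson", random_effects=True, quadrature_points=q),
                p,
                small_table,
            )
            for q in (7, 15, 25)
        }
        # converged by 15 nodes; 7 nodes is close but not to 1e-4 over
        # hundreds of blocks
        assert abs(lls[25] - lls[15]) < 1e-4
        assert abs(lls[25] - lls[7]) < 0.05

    def test_dimension_mismatch_raises(self, small_table):
        spec = ModelSpec(family="poisson")
        with pytest.raises(ValueError):
            marginal_loglik(spec, ModelParams(beta=np.zeros(3)), small_table)


# ---------------------------------------------------------------------------
# fitting against independent GLM oracles
# ---------------------------------------------------------------------------


def _design(table):
    X = sm.add_constant(table[["x1", "x2", "x3"]].to_numpy())
    return table["y"].to_numpy(), X, np.log(table["n_tests"].to_numpy())


class TestFitOracles:
    def test_poisson_matches_glm(self, fixture_table):
        res = fit(ModelSpec(family="poisson"), fixture_table)
        y, X, off = _design(fixture_table)
        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        np.testing.assert_allclose(res.params.beta, glm.params, rtol=1e-4)
        np.testing.assert_allclose(res.se.beta, glm.bse, rtol=1e-3)
        assert res.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_nb_matches_discrete_nb(self, fixture_table):
        res = fit(ModelSpec(family="nb"), fixture_table)
        y, X, off = _design(fixture_table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oracle = sm.NegativeBinomial(y, X, offset=off).fit(
                start_params=np.r_[res.params.beta, res.params.kappa],
                method="bfgs",
                maxiter=500,
                disp=0,
            )
        np.testing.assert_allclose(res.params.beta, oracle.params[:4], rtol=1e-4, atol=1e-6)
        assert res.params.kappa == pytest.approx(oracle.params[4], rel=1e-3)
        assert res.loglik >= oracle.llf - 1e-6

    def test_hurdle_poisson_matches_two_part_oracle(self, fixture_table):
        res = fit(ModelSpec(family="hurdle_poisson"), fixture_table)
        y, X, off = _design(fixture_table)
        logit = sm.Logit((y == 0).astype(float), X).fit(disp=0)
        pos = y >= 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tp = TruncatedLFPoisson(
                y[pos], X[pos], offset=off[pos], truncation=0
            ).fit(start_params=res.params.beta, method="bfgs", maxiter=500, disp=0)
        np.testing.assert_allclose(res.params.alpha, logit.params, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(res.params.beta, tp.params, rtol=1e-4, atol=1e-6)
        # factorization: joint loglik = logistic + truncated
        assert res.loglik == pytest.approx(logit.llf + tp.llf, abs=1e-4)

    def test_hurdle_nb_matches_two_part_oracle(self, fixture_table):
        res = fit(ModelSpec(family="hurdle_nb"), fixture_table)
        y, X, off = _design(fixture_table)
        logit = sm.Logit((y == 0).astype(float), X).fit(disp=0)
        pos = y >= 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tnb = TruncatedLFNegativeBinomialP(
                y[pos], X[pos], offset=off[pos], truncation=0, p=2
            ).fit(
                start_params=np.r_[res.params.beta, res.params.kappa],
                method="bfgs",
                maxiter=500,
                disp=0,
            )
        np.testing.assert_allclose(res.params.alpha, logit.params, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(res.params.beta, tnb.params[:4], rtol=1e-3, atol=1e-6)
        assert res.loglik >= logit.llf + tnb.llf - 1e-4

    def test_intercept_only_closed_form(self):
        table = make_table([3, 0, 1], [10, 5, 8])
        res = fit(ModelSpec(family="poisson", covariate_columns=()), table)
        assert res.params.beta[0] == pytest.approx(np.log(4.0 / 23.0), abs=1e-8)


class TestFitStructure:
    @pytest.mark.parametrize(
        "family,expected",
        [("poisson", 5), ("nb", 6), ("hurdle_poisson", 10), ("hurdle_nb", 11)],
    )
    def test_n_params_re_families(self, family, expected):
        assert ModelSpec(family=family, random_effects=True).n_params == expected

    @pytest.mark.parametrize(
        "family,expected",
        [("poisson", 4), ("nb", 5), ("hurdle_poisson", 8), ("hurdle_nb", 9)],
    )
    def test_n_params_fixed_effects(self, family, expected):
        assert ModelSpec(family=family, random_effects=False).n_params == expected

    def test_aic_identity_on_fit(self, fixture_table):
        res = fit(ModelSpec(family="poisson"), fixture_table)
        assert res.aic == -2.0 * res.loglik + 2.0 * res.n_params

    def test_even_quadrature_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(quadrature_points=4)

    def test_hurdle_requires_zero_and_positive(self):
        table = make_table([1, 2, 3], [5, 5, 5])
        with pytest.raises(ValueError):
            fit(ModelSpec(family="hurdle_poisson"), table)

    def test_kappa_small_when_data_poisson(self):
        from blockcount.synthetic_data import SimulationConfig, simulate_dataset
        import dataclasses

        cfg = SimulationConfig(
            n_blocks=10000,
            grid_shape=(100, 100),
            family="poisson",
            beta=(10.4, -0.007, -0.35, 0.15),
            seed=42,
        )
        table, _ = simulate_dataset(cfg)
        res = fit(ModelSpec(family="nb"), table)
        assert res.params.kappa < 0.05

    def test_poisson_re_recovery_single_replicate(self):
        from blockcount.synthetic_data import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_blocks=1393,
            grid_shape=(38, 37),
            family="poisson",
            beta=(10.4, -0.007, -0.35, 0.15),
            sigma2=0.5,
            seed=5,
        )
        table, _ = simulate_dataset(cfg)
        res = fit(ModelSpec(family="poisson", random_effects=True), table)
        assert res.converged
        truth = np.r_[cfg.beta]
        err = np.abs(res.params.beta - truth)
        assert np.all(err < 4.0 * res.se.beta)
        assert abs(res.params.sigma2 - 0.5) < 4.0 * res.se.sigma2

    def test_coef_table_shape(self, fixture_table):
        res = fit(ModelSpec(family="hurdle_nb", random_effects=False), fixture_table)
        tab = res.coef_table()
        assert set(tab["part"]) == {"count", "zero", "dispersion"}
        assert len(tab) == 9


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


class TestPredict:
    def test_fixed_effects_poisson_is_glm_mean(self, fixture_table):
        res = fit(ModelSpec(family="poisson"), fixture_table)
        pred = predict_expected_counts(res, fixture_table, mode="marginal")
        eta = (
            res.params.beta[0]
            + fixture_table[["x1", "x2", "x3"]].to_numpy() @ res.params.beta[1:]
            + np.log(fixture_table["n_tests"].to_numpy())
        )
        np.testing.assert_allclose(pred, np.exp(eta), rtol=1e-10)

    def test_marginal_re_mean_matches_monte_carlo(self):
        # E[e^{x'b + gamma}] = e^{x'b + s2/2}; check against simulation
        rng = np.random.default_rng(21)
        big = make_table(rng.poisson(1.0, 40), rng.integers(1, 30, 40))
        res = fit(ModelSpec(family="poisson", random_effects=True), big)
        table = big.iloc[:2]
        res.params.sigma2 = 0.49
        pred = predict_expected_counts(res, table, mode="marginal")
        rng = np.random.default_rng(3)
        gam = rng.normal(0, 0.7, 10**6)
        X = table[["x1", "x2", "x3"]].to_numpy()
        base = np.exp(
            res.params.beta[0] + X @ res.params.beta[1:]
        ) * table["n_tests"].to_numpy()
        mc = base * np.exp(gam).mean()
        mc_se = base * np.exp(gam).std() / 1000.0
        assert np.all(np.abs(pred - mc) < 3 * mc_se)

    def test_hurdle_marginal_matches_monte_carlo(self, fixture_table):
        res = fit(
            ModelSpec(family="hurdle_nb", random_effects=True, quadrature_points=7),
            fixture_table.iloc[:80],
        )
        sub = fixture_table.iloc[:5]
        pred = predict_expected_counts(res, sub, mode="marginal")
        rng = np.random.default_rng(9)
        n_mc = 400000
        gz = rng.normal(0, np.sqrt(res.params.sigma2_zero), n_mc)
        g = rng.normal(0, np.sqrt(max(res.params.sigma2, 1e-12)), n_mc)
        X = sub[["x1", "x2", "x3"]].to_numpy()
        from scipy.special import expit

        from blockcount.likelihoods import _log1mexp, _log_p0

        kap = res.params.kappa
        for i in range(len(sub)):
            pa = res.params.alpha[0] + X[i] @ res.params.alpha[1:]
            pb = (
                res.params.beta[0]
                + X[i] @ res.params.beta[1:]
                + np.log(sub["n_tests"].to_numpy()[i])
            )
            prob_pos = (1.0 - expit(pa + gz)).mean()
            mu = np.exp(pb + g)
            tmean = np.exp(np.log(mu) - _log1mexp(_log_p0(mu, kap)))
            mc = prob_pos * tmean.mean()
            se = abs(mc) * 3.0 / np.sqrt(n_mc) + 3 * prob_pos * tmean.std() / np.sqrt(n_mc)
            assert abs(pred[i] - mc) < max(se, 2e-3)

    def test_hurdle_certain_zero_predicts_zero(self, fixture_table):
        res = fit(ModelSpec(family="hurdle_poisson"), fixture_table.iloc[:80])
        res.params.alpha = np.array([60.0, 0.0, 0.0, 0.0])  # p0 -> 1 everywhere
        pred = predict_expected_counts(res, fixture_table.iloc[:5], mode="marginal")
        assert np.all(pred < 1e-6)

    def test_conditional_out_of_sample_rejected(self, fixture_table):
        res = fit(
            ModelSpec(family="poisson", random_effects=True), fixture_table.iloc[:60]
        )
        with pytest.raises(ValueError, match="marginal"):
            predict_expected_counts(res, fixture_table.iloc[60:70], mode="conditional")

    def test_conditional_uses_eb_estimates(self, fixture_table):
        sub = fixture_table.iloc[:60].reset_index(drop=True)
        res = fit(ModelSpec(family="poisson", random_effects=True), sub)
        cond = predict_expected_counts(res, sub, mode="conditional")
        marg = predict_expected_counts(res, sub, mode="marginal")
        # EB predictions track the data more closely than marginal ones
        y = sub["y"].to_numpy()
        assert np.mean(np.abs(y - cond)) < np.mean(np.abs(y - marg))
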