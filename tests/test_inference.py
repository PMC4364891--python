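"""MCMC protocol, convergence diagnostics, DIC and the posterior predictive check."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hbdsm import (
    CetaceanDensityModel,
    HabitatParams,
    McmcConfig,
    bayesian_pvalue,
    dic,
    gelman_rubin,
    mc_error,
)
from hbdsm.density import g0_prior
from hbdsm.inference import PosteriorResult

from conftest import TRUE_REFERENCE_MEAN, quick_fit, small_whale_config
from hbdsm import simulate_survey


def make_result(draws, deviance_at_means=0.0, deviance_draws=None,
                disc_obs=None, disc_rep=None, n_counts=None,
                habitat_form="poly2", reference_mean=66.0,
                adt_range=(40.0, 90.0)):
    """Assemble a PosteriorResult from raw draw arrays for diagnostic tests."""
    draws = {k: np.asarray(v, dtype=float) for k, v in draws.items()}
    shape = next(iter(draws.values())).shape
    zeros = np.zeros(shape)
    return PosteriorResult(
        draws={k: np.asarray(v, dtype=float) for k, v in draws.items()},
        lambda_draws=np.zeros((*shape, 1)),
        deviance_draws=zeros if deviance_draws is None else np.asarray(deviance_draws),
        deviance_at_means=deviance_at_means,
        discrepancy_obs=zeros if disc_obs is None else np.asarray(disc_obs),
        discrepancy_rep=zeros if disc_rep is None else np.asarray(disc_rep),
        random_effect_means={},
        species_form="whale_like", habitat_form=habitat_form,
        adt_reference_mean=reference_mean, adt_fitted_range=adt_range,
        config=McmcConfig(seed=0),
        g0_prior=g0_prior(0.921, 0.023),
        n_counts=np.zeros(1, dtype=int) if n_counts is None else n_counts,
    )


class TestMcmcConfig:
    def test_default_retained_sample(self):
        assert McmcConfig().retained_per_chain == 800

    def test_invariants(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=100, n_burnin=100)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)
        with pytest.raises(ValueError):
            McmcConfig(n_chains=0)


class TestGelmanRubin:
    def test_identical_chains(self):
        x = np.random.default_rng(0).normal(size=500)
        # the finite-sample estimator gives sqrt((n-1)/n) when B = 0
        assert gelman_rubin(np.tile(x, (3, 1))) == pytest.approx(1.0, abs=2e-3)

    def test_chains_from_same_distribution(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(3, 10_000))
        assert gelman_rubin(draws) < 1.01

    def test_disjoint_chains(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(2, 500)) + np.array([[0.0], [100.0]])
        assert gelman_rubin(draws) > 10

    def test_chain_order_invariance(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(4, 200)) + rng.normal(size=(4, 1))
        assert gelman_rubin(draws) == pytest.approx(
            gelman_rubin(draws[::-1]), rel=1e-14)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_against_arviz_oracle(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        draws = rng.normal(size=(3, 5000))
        mine = gelman_rubin(draws)
        theirs = float(arviz.rhat(arviz.convert_to_dataset(draws[..., None])
                                  ).to_array().values.squeeze())
        assert mine == pytest.approx(theirs, abs=0.01)


class TestMcError:
    def test_constant_draws(self):
        assert mc_error(np.full(1000, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_iid_square_root_law(self):
        rng = np.random.default_rng(5)
        s = 2.0
        draws = rng.normal(0.0, s, size=10_000)
        assert mc_error(draws) == pytest.approx(s / 100.0, rel=0.2)

    def test_bounded_by_posterior_sd(self):
        rng = np.random.default_rng(6)
        draws = np.cumsum(rng.normal(size=5000)) * 0.01 + rng.normal(size=5000)
        assert mc_error(draws) <= draws.std(ddof=1)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            mc_error(np.arange(10))


class TestBayesianPvalue:
    def test_ties_split_evenly(self):
        t = np.abs(np.random.default_rng(7).normal(size=(2, 100)))
        result = make_result({"omega0": np.zeros((2, 100))},
                             disc_obs=t, disc_rep=t.copy())
        assert bayesian_pvalue(result) == pytest.approx(0.5)

    def test_direction(self):
        obs = np.full((1, 200), 10.0)
        rep = np.concatenate([np.full((1, 150), 20.0), np.full((1, 50), 5.0)],
                             axis=1)
        result = make_result({"omega0": np.zeros((1, 200))},
                             disc_obs=obs, disc_rep=rep)
        assert bayesian_pvalue(result) == pytest.approx(0.75)


class TestDic:
    def test_degenerate_posterior_has_zero_complexity(self):
        dev = np.full((2, 100), 123.4)
        result = make_result({"omega0": np.full((2, 100), -5.0)},
                             deviance_draws=dev, deviance_at_means=123.4)
        d, p_d, dbar = dic(result)
        assert p_d == pytest.approx(0.0, abs=1e-10)
        assert d == pytest.approx(123.4)
        assert dbar == pytest.approx(123.4)

    def test_positive_complexity_on_real_fit(self, whale_fit):
        d, p_d, dbar = dic(whale_fit.result_)
        assert p_d > 0
        assert d == pytest.approx(dbar + p_d)


class TestFittedModel:
    def test_retained_draw_count(self, whale_fit):
        r = whale_fit.result_
        n_ret = (3000 - 1000) // 5
        for v in r.draws.values():
            assert v.shape == (3, n_ret)

    def test_summary_layout_and_quantile_ordering(self, whale_fit):
        s = whale_fit.summary_
        assert list(s.columns) == ["mean", "sd", "q2.5", "median", "q97.5",
                                   "mc_error", "rhat"]
        assert (s["q2.5"] <= s["median"]).all()
        assert (s["median"] <= s["q97.5"]).all()
        assert (s["mc_error"] >= 0).all()
        assert (s["mc_error"] <= s["sd"] + 1e-12).all()

    def test_exchanging_chain_order_leaves_summaries_unchanged(self, whale_fit):
        r = whale_fit.result_
        flipped = make_result({k: v[::-1] for k, v in r.draws.items()})
        for name in r.draws:
            a = r.summary().loc[name]
            b = flipped.summary().loc[name]
            for col in ("mean", "sd", "q2.5", "median", "q97.5", "rhat"):
                assert a[col] == pytest.approx(b[col], rel=1e-9), (name, col)

    def test_deterministic_given_seed(self, whale_survey):
        sv = whale_survey
        kw = dict(n_iterations=300, n_burnin=100, thin=4, n_chains=2, seed=11)
        a = quick_fit(sv.cells, sv.sightings, **kw)
        b = quick_fit(sv.cells, sv.sightings, **kw)
        for name in a.result_.draws:
            np.testing.assert_array_equal(a.result_.draws[name],
                                          b.result_.draws[name])

    def test_sklearn_style_params(self):
        m = CetaceanDensityModel(seed=3)
        params = m.get_params()
        assert params["seed"] == 3
        m.set_params(habitat_form="poly3")
        assert m.habitat_form == "poly3"
        with pytest.raises(ValueError):
            m.set_params(nonsense=1)

    def test_empty_inputs_rejected(self, whale_survey):
        m = CetaceanDensityModel(n_iterations=200, n_burnin=50)
        with pytest.raises(ValueError, match="sightings"):
            m.fit(whale_survey.cells, whale_survey.sightings.iloc[:0])
        with pytest.raises(ValueError, match="effort"):
            m.fit(whale_survey.cells.assign(effort_km=0.0),
                  whale_survey.sightings)


class TestMisspecificationDetection:
    def test_overdispersed_counts_fail_the_predictive_check(self):
        """Counts with strong unmodelled log-normal heterogeneity give p ~ 0."""
        cfg = small_whale_config(
            31,
            true_habitat=HabitatParams(omega=(-6.6, -16.2, -46.88),
                                       theta=(-6.6, -16.2, -46.88, 0.0),
                                       sigma_eps2=1.6,
                                       adt_reference_mean=TRUE_REFERENCE_MEAN),
        )
        sv = simulate_survey(cfg)
        m = quick_fit(sv.cells, sv.sightings, n_iterations=1500, n_burnin=600,
                      sigma_e1_fixed=0.0, sigma_e2_fixed=0.0, seed=31)
        assert m.bayesian_pvalue_ < 0.05
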