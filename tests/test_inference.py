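"""Likelihood, prior, sampler, diagnostics and information-criterion tests."""

import numpy as np
import pandas as pd
import pytest

from microdev.data import LayerTimeSeries
from microdev.inference import (
    ChainSet,
    ModelLikelihood,
    ModelScore,
    ParameterSpace,
    PriorBounds,
    default_bounds,
    information_criteria,
    log_prior,
    posterior_summary,
    rank_models,
    run_adaptive_mh,
)
from microdev.models import SolverConfig, TwoPopParams, VolumeParams
from microdev.topology import RegionTopology

BOX_1D = np.array([[-10.0, 10.0]])


def _toy_dataset(values=None):
    """Three density observations at two ages on one layer."""
    rows = []
    vals = values if values is not None else [5.0, 5.0, 5.0]
    for (age, rep), v in zip([(0.0, 1), (0.0, 2), (1.0, 1)], vals):
        rows.append({"region": "toy", "layer": "L", "age_days": age,
                     "replicate": rep, "observable": "density", "value": v})
    return LayerTimeSeries("toy", pd.DataFrame(rows))


def _toy_likelihood(values=None, sigma=1.0):
    topo = RegionTopology("toy", ("L",))
    params = TwoPopParams(A0={"L": 5.0}, volume={"L": VolumeParams(1.0, 1.0, 0.0)})
    space = ParameterSpace(
        "two_pop", topo, params, ("sigma_density",),
        base_sigmas={"volume": 1.0, "density": sigma, "pct_ki67": 1.0},
    )
    return ModelLikelihood(_toy_dataset(values), space, SolverConfig())


class TestLikelihood:
    def test_zero_residual_normal_constant(self):
        # all rates zero: prediction stays at A0=5 and matches the data
        lik = _toy_likelihood()
        total, pointwise = lik(np.array([1.0]))
        assert total == pytest.approx(-1.5 * np.log(2 * np.pi), abs=1e-12)
        assert pointwise.shape == (3,)

    def test_doubling_sigma_costs_n_log2(self):
        lik = _toy_likelihood()
        ll1, _ = lik(np.array([1.0]))
        ll2, _ = lik(np.array([2.0]))
        assert ll1 - ll2 == pytest.approx(3 * np.log(2), rel=1e-12)

    def test_total_equals_pointwise_sum(self):
        rng = np.random.default_rng(7)
        lik = _toy_likelihood(values=list(rng.uniform(0, 10, 3)))
        total, pointwise = lik(np.array([1.7]))
        assert total == pytest.approx(pointwise.sum(), abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        lik = _toy_likelihood()
        total, pointwise = lik(np.array([0.0]))
        assert total == -np.inf and pointwise is None


class TestPrior:
    def test_constant_inside_box(self):
        lo, hi = np.array([0.0, 0.0]), np.array([2.0, 4.0])
        v1 = log_prior(np.array([0.1, 3.9]), lo, hi)
        v2 = log_prior(np.array([1.9, 0.1]), lo, hi)
        assert v1 == v2 == pytest.approx(-np.log(8.0))

    def test_outside_is_minus_inf(self):
        lo, hi = np.array([0.0]), np.array([1.0])
        assert log_prior(np.array([-0.01]), lo, hi) == -np.inf
        assert log_prior(np.array([1.01]), lo, hi) == -np.inf

    def test_halving_interval_raises_by_log2(self):
        lo = np.array([0.0])
        assert (
            log_prior(np.array([0.2]), lo, np.array([0.5]))
            - log_prior(np.array([0.2]), lo, np.array([1.0]))
        ) == pytest.approx(np.log(2))

    def test_missing_bound_is_configuration_error(self):
        pb = PriorBounds({"a": (0.0, 1.0)})
        with pytest.raises(KeyError, match="b"):
            pb.as_arrays(["a", "b"])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorBounds({"a": (1.0, 1.0)})
        with pytest.raises(ValueError):
            PriorBounds({"a": (-0.5, 1.0)})


class TestSampler:
    def test_same_seed_bit_identical(self):
        target = lambda th: -0.5 * th[0] ** 2
        a = run_adaptive_mh(target, BOX_1D, n_chains=3, n_iter=2000, seed=42)
        b = run_adaptive_mh(target, BOX_1D, n_chains=3, n_iter=2000, seed=42)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.log_posterior, b.log_posterior)

    def test_different_seeds_differ(self):
        target = lambda th: -0.5 * th[0] ** 2
        a = run_adaptive_mh(target, BOX_1D, n_chains=3, n_iter=2000, seed=1)
        b = run_adaptive_mh(target, BOX_1D, n_chains=3, n_iter=2000, seed=2)
        assert not np.array_equal(a.draws, b.draws)

    def test_preconditions(self):
        target = lambda th: 0.0
        with pytest.raises(ValueError):
            run_adaptive_mh(target, BOX_1D, n_chains=2, n_iter=2000, seed=0)
        with pytest.raises(ValueError):
            run_adaptive_mh(target, BOX_1D, n_chains=3, n_iter=500, seed=0)

    def test_standard_normal_moments(self):
        # quadrature oracle: restricted N(0,1) has mean 0, sd ~1 on [-10,10]
        target = lambda th: -0.5 * th[0] ** 2
        cs = run_adaptive_mh(target, BOX_1D, n_chains=3, n_iter=5000, seed=3)
        pooled = cs.retained()[:, 0]
        mcse = pooled.std() / np.sqrt(len(pooled) / 20)  # crude ESS deflation
        assert abs(pooled.mean()) < 3 * mcse
        assert pooled.std() == pytest.approx(1.0, rel=0.1)


class TestSummary:
    def _constant_chainset(self, value=2.5):
        draws = np.full((3, 2000, 1), value)
        return ChainSet(
            draws=draws, log_posterior=np.zeros((3, 2000)),
            loglik=np.zeros((3, 2000)), acceptance_rate=np.full(3, 0.5),
            seed=0, burn_in=1000, param_names=("p",),
        )

    def test_constant_chains_degenerate_summary(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = posterior_summary(self._constant_chainset())
        assert s.loc["p", "sd"] == 0.0
        assert s.loc["p", "q2.5"] == s.loc["p", "q97.5"] == 2.5
        assert s.loc["p", "rhat"] == 1.0

    def test_nonmixing_chains_flagged(self):
        rng = np.random.default_rng(0)
        draws = np.stack([
            rng.normal(0, 1, (2000, 1)),
            rng.normal(10, 1, (2000, 1)),
            rng.normal(0, 1, (2000, 1)),
        ])
        cs = ChainSet(
            draws=draws, log_posterior=np.zeros((3, 2000)),
            loglik=np.zeros((3, 2000)), acceptance_rate=np.full(3, 0.4),
            seed=0, burn_in=1000, param_names=("p",),
        )
        s = posterior_summary(cs)
        assert s.loc["p", "rhat"] > 1.05 and not s.loc["p", "converged"]

    def test_median_near_zero_on_normal_target(self):
        target = lambda th: -0.5 * th[0] ** 2
        cs = run_adaptive_mh(target, BOX_1D, n_chains=3, n_iter=5000, seed=9)
        s = posterior_summary(cs)
        assert abs(s.loc["p0", "q50"]) < 0.1


def _chainset_with_pointwise(pointwise, loglik=None):
    n_chains, n_iter, n_obs = pointwise.shape
    return ChainSet(
        draws=np.zeros((n_chains, n_iter, 2)),
        log_posterior=np.zeros((n_chains, n_iter)),
        loglik=loglik if loglik is not None else pointwise.sum(axis=2),
        acceptance_rate=np.full(n_chains, 0.3),
        seed=0, burn_in=0, param_names=("a", "b"),
        pointwise_loglik=pointwise,
    )


class TestInformationCriteria:
    def test_aic_formula(self):
        s = ModelScore("m", max_loglik=-10, aic=26, bic=3 * np.log(20) + 20,
                       waic=0.0, n_params=3, n_obs=20, effective_params_waic=0.0)
        assert s.aic == 26

    def test_identity_violation_rejected(self):
        with pytest.raises(ValueError):
            ModelScore("m", max_loglik=-10, aic=20, bic=3 * np.log(20) + 20,
                       waic=0.0, n_params=3, n_obs=20, effective_params_waic=0.0)

    def test_bic_formula_through_chains(self):
        pw = np.tile(np.array([-1.0, -2.0, -0.5, -3.0, -3.5]), (3, 10, 1))
        cs = _chainset_with_pointwise(pw)
        score = information_criteria(cs, "toy")
        # max loglik = -10, n_params=2, n_obs=5
        assert score.aic == pytest.approx(2 * 2 + 20)
        assert score.bic == pytest.approx(2 * np.log(5) + 20)

    def test_degenerate_posterior_waic_penalty_zero(self):
        pw = np.tile(np.array([-1.0, -2.0, -0.5]), (3, 10, 1))
        score = information_criteria(_chainset_with_pointwise(pw), "toy")
        assert score.effective_params_waic == pytest.approx(0.0, abs=1e-12)
        assert score.waic == pytest.approx(-2 * (-3.5), rel=1e-12)

    def test_waic_matches_brute_force(self):
        # explicit double loop over draws and observations, to 1e-10
        rng = np.random.default_rng(5)
        pw = rng.normal(-2, 0.5, size=(2, 5, 5))  # 10 retained draws, 5 obs
        cs = ChainSet(
            draws=np.zeros((2, 5, 2)), log_posterior=np.zeros((2, 5)),
            loglik=pw.sum(axis=2), acceptance_rate=np.full(2, 0.3),
            seed=0, burn_in=0, param_names=("a", "b"), pointwise_loglik=pw,
        )
        flat = cs.retained_pointwise()  # (10, 5)
        lppd = 0.0
        penalty = 0.0
        for i in range(flat.shape[1]):
            liks = [np.exp(flat[s, i]) for s in range(flat.shape[0])]
            lppd += np.log(np.mean(liks))
            lls = [flat[s, i] for s in range(flat.shape[0])]
            mean_ll = sum(lls) / len(lls)
            penalty += sum((x - mean_ll) ** 2 for x in lls) / (len(lls) - 1)
        expected = -2.0 * (lppd - penalty)
        score = information_criteria(cs, "toy")
        assert score.waic == pytest.approx(expected, abs=1e-10)

    def test_waic_needs_two_draws(self):
        pw = np.zeros((3, 2, 4))
        cs = _chainset_with_pointwise(pw)
        cs.burn_in = 2
        with pytest.raises(ValueError):
            information_criteria(cs)


class TestRanking:
    def _score(self, model_id, ll, n_params, n_obs=20, waic=10.0):
        return ModelScore(
            model_id, max_loglik=ll, aic=2 * n_params - 2 * ll,
            bic=n_params * np.log(n_obs) - 2 * ll, waic=waic,
            n_params=n_params, n_obs=n_obs, effective_params_waic=1.0,
        )

    def test_penalty_ordering_on_equal_likelihood(self):
        lean = self._score("lean", -10, 3, waic=20)
        fat = self._score("fat", -10, 6, waic=20.5)
        ranking = rank_models([lean, fat])
        assert ranking["aic"][0] == "lean" and ranking["bic"][0] == "lean"
        assert ranking["consensus"] == "lean"

    def test_discordant_criteria_labeled(self):
        a = self._score("a", -10, 3, waic=30)
        b = self._score("b", -11, 3, waic=10)
        assert rank_models([a, b])["consensus"] == "discordant"

    def test_single_model_trivial(self):
        s = self._score("only", -5, 2)
        assert rank_models([s])["consensus"] == "only"

    def test_incomparable_data_sizes(self):
        with pytest.raises(ValueError):
            rank_models([self._score("a", -5, 2, n_obs=10),
                         self._score("b", -5, 2, n_obs=20)])


class TestParameterSpaceAndBounds:
    def test_dotted_paths_and_specials(self):
        topo = RegionTopology("r", ("L",))
        base = TwoPopParams(A0={"L": 1.0}, volume={"L": VolumeParams(1.0, 2.0, 0.1)})
        space = ParameterSpace(
            "two_pop", topo, base,
            ("a1_int_A", "A0.L", "volume.L.g", "tau_k", "sigma_density"),
        )
        params, tau_k, sigmas = space.build(np.array([0.9, 55.0, 0.4, 0.3, 7.0]))
        assert params.a1_int_A == 0.9
        assert params.A0["L"] == 55.0
        assert params.volume["L"].g == 0.4
        assert tau_k == 0.3 and sigmas["density"] == 7.0

    def test_unknown_path_rejected(self):
        topo = RegionTopology("r", ("L",))
        base = TwoPopParams(A0={"L": 1.0}, volume={"L": VolumeParams(1.0, 2.0, 0.1)})
        with pytest.raises(KeyError):
            ParameterSpace("two_pop", topo, base, ("nonexistent_rate",))

    def test_default_bounds_rules(self):
        data = _toy_dataset([100.0, 120.0, 90.0])
        topo = RegionTopology("toy", ("L",))
        base = TwoPopParams(A0={"L": 100.0}, volume={"L": VolumeParams(1.0, 1.0, 0.0)})
        space = ParameterSpace(
            "two_pop", topo, base, ("a1_int_A", "A0.L", "sigma_density", "tau_k")
        )
        b = default_bounds(space, data).bounds
        assert b["a1_int_A"] == (0.0, 10.0)
        assert b["A0.L"] == (0.0, 1200.0)  # 10x observed max density
        assert b["tau_k"][1] == 1.5
        sd = np.std([100.0, 120.0, 90.0], ddof=1)
        assert b["sigma_density"][1] == pytest.approx(10 * sd)
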