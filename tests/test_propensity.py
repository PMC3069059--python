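"""Tests of the four propensity estimators and the balance statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from pstrim import (BoostParams, CartParams, ForestParams, SimulatedDataset,
                    clip_propensity, fit_boosted_cart, fit_cart,
                    fit_logistic_main_effects, fit_propensity,
                    fit_random_forest, odds_weights, weighted_ks_statistic)


def toy_dataset(covariates, exposure, seed=0):
    covariates = np.asarray(covariates, dtype=float)
    n = covariates.shape[0]
    p = np.full(n, 0.5)
    return SimulatedDataset(covariates=covariates,
                            exposure=np.asarray(exposure),
                            outcome=np.zeros(n), true_propensity=p,
                            seed=seed, scenario_id=1)


def brute_force_ks(x, group, weights):
    """Independent oracle: evaluate both weighted ECDFs at every data
    point with an explicit double loop."""
    x = np.asarray(x, float)
    w1 = np.sum(weights[group == 1])
    w0 = np.sum(weights[group == 0])
    best = 0.0
    for t in x:
        f1 = sum(wi for xi, gi, wi in zip(x, group, weights)
                 if gi == 1 and xi <= t) / w1
        f0 = sum(wi for xi, gi, wi in zip(x, group, weights)
                 if gi == 0 and xi <= t) / w0
        best = max(best, abs(f1 - f0))
    return best


class TestWeightedKS:
    def test_identical_distributions(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array([1, 1, 1, 0, 0, 0])
        assert weighted_ks_statistic(x, g, np.ones(6)) == 0.0

    def test_disjoint_supports(self):
        x = np.array([1.0, 2.0, 10.0, 11.0])
        g = np.array([1, 1, 0, 0])
        assert weighted_ks_statistic(x, g, np.ones(4)) == 1.0

    def test_four_point_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert weighted_ks_statistic(x, np.array([1, 1, 0, 0]),
                                     np.ones(4)) == 1.0
        assert weighted_ks_statistic(x, np.array([1, 0, 1, 0]),
                                     np.ones(4)) == 0.5

    def test_zero_weight_group_is_an_error(self):
        x = np.arange(4.0)
        g = np.array([1, 1, 0, 0])
        with pytest.raises(ValueError, match="control"):
            weighted_ks_statistic(x, g, np.array([1.0, 1.0, 0.0, 0.0]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        x = np.round(rng.normal(size=n), 1)  # ties on purpose
        g = rng.integers(0, 2, n)
        if g.sum() in (0, n):
            g[0] = 1 - g[0]
        w = rng.uniform(0.1, 5.0, n)
        fast = weighted_ks_statistic(x, g, w)
        slow = brute_force_ks(x, g, w)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_unit_weights_match_classical_ks(self, rng):
        from scipy.stats import ks_2samp
        x = rng.normal(size=40)
        g = np.r_[np.ones(20, int), np.zeros(20, int)]
        classical = ks_2samp(x[g == 1], x[g == 0]).statistic
        assert weighted_ks_statistic(x, g, np.ones(40)) == pytest.approx(
            classical, abs=1e-12)


class TestClip:
    def test_interior_unchanged(self):
        out = clip_propensity(np.array([0.5, 0.2, 0.8]), 1e-3)
        np.testing.assert_array_equal(out, [0.5, 0.2, 0.8])

    def test_boundary_clipped(self):
        out = clip_propensity(np.array([0.0, 1.0]), 0.001)
        np.testing.assert_allclose(out, [0.001, 0.999])

    def test_bad_epsilon(self):
        with pytest.raises(ValueError):
            clip_propensity(np.array([0.5]), 0.7)


class TestLogistic:
    def test_recovers_true_propensity_ranks(self, dataset1):
        fit = fit_logistic_main_effects(dataset1)
        rho = spearmanr(fit.propensity, dataset1.true_propensity).statistic
        assert rho > 0.9
        assert fit.metadata["converged"]

    def test_null_model_coefficients_near_zero(self):
        from conftest import make_spec
        from pstrim import simulate_dataset
        spec = make_spec(exposure_main_coefs=(0.0,) * 10)
        ds = simulate_dataset(spec, 2000, seed=9)
        fit = fit_logistic_main_effects(ds)
        slopes = fit.metadata["params"][1:]
        bse = fit.metadata["bse"][1:]
        assert np.all(np.abs(slopes) < 3 * bse)

    def test_deterministic(self, dataset1):
        a = fit_logistic_main_effects(dataset1)
        b = fit_logistic_main_effects(dataset1)
        np.testing.assert_array_equal(a.propensity, b.propensity)

    def test_permutation_equivariance(self, dataset1, rng):
        import dataclasses
        perm = rng.permutation(dataset1.n)
        permuted = SimulatedDataset(
            covariates=dataset1.covariates[perm],
            exposure=dataset1.exposure[perm],
            outcome=dataset1.outcome[perm],
            true_propensity=dataset1.true_propensity[perm],
            seed=dataset1.seed, scenario_id=dataset1.scenario_id)
        a = fit_logistic_main_effects(dataset1)
        b = fit_logistic_main_effects(permuted)
        np.testing.assert_allclose(b.propensity, a.propensity[perm],
                                   atol=1e-8)


class TestCart:
    def test_pure_nodes_are_clipped(self):
        x = np.zeros((100, 10))
        x[:, 0] = np.linspace(-1, 1, 100)
        ds = toy_dataset(x, (x[:, 0] >= 0).astype(int))
        fit = fit_cart(ds, CartParams(min_samples_split=2,
                                      min_samples_leaf=1))
        assert set(np.round(fit.propensity, 6)) == {0.001, 0.999}
        assert set(np.round(fit.raw_propensity, 6)) == {0.0, 1.0}

    def test_constant_covariates_give_prevalence(self):
        x = np.ones((60, 10))
        exposure = np.r_[np.ones(20, int), np.zeros(40, int)]
        ds = toy_dataset(x, exposure)
        fit = fit_cart(ds)
        np.testing.assert_allclose(fit.propensity, 20 / 60)
        assert fit.metadata["n_leaves"] == 1

    def test_node_proportions_match_hand_count(self):
        # 12 points, one binary covariate: leaves are the two x values;
        # treated fractions are 4/6 and 1/6
        x = np.zeros((12, 10))
        x[:6, 0] = 1.0
        exposure = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 1, 0, 0])
        ds = toy_dataset(x, exposure)
        fit = fit_cart(ds, CartParams(min_samples_split=2,
                                      min_samples_leaf=1))
        np.testing.assert_allclose(fit.propensity[:6], 4 / 6)
        np.testing.assert_allclose(fit.propensity[6:], 1 / 6)


class TestRandomForest:
    def test_single_tree_no_bootstrap_equals_cart(self, dataset1):
        cart = fit_cart(dataset1, CartParams(min_samples_split=20,
                                             min_samples_leaf=7, seed=1))
        forest = fit_random_forest(
            dataset1, ForestParams(n_trees=1, max_features=None,
                                   bootstrap=False, min_samples_leaf=7,
                                   min_samples_split=20, seed=1))
        np.testing.assert_allclose(forest.propensity, cart.propensity)

    def test_saturated_votes_clipped(self):
        x = np.zeros((80, 10))
        x[:, 0] = np.linspace(-1, 1, 80)
        ds = toy_dataset(x, (x[:, 0] >= 0).astype(int))
        fit = fit_random_forest(ds, ForestParams(n_trees=25, bootstrap=False,
                                                 max_features=None, seed=0))
        assert fit.raw_propensity.max() == 1.0
        assert fit.propensity.max() == 0.999

    def test_deterministic_given_seed(self, dataset1):
        a = fit_random_forest(dataset1, ForestParams(n_trees=50, seed=3))
        b = fit_random_forest(dataset1, ForestParams(n_trees=50, seed=3))
        np.testing.assert_array_equal(a.propensity, b.propensity)

    def test_oob_probabilities_are_not_memorized(self, dataset1):
        # with bootstrap, training-set probabilities come from out-of-bag
        # trees, so they must not reproduce the labels
        fit = fit_random_forest(dataset1, ForestParams(n_trees=100, seed=0))
        agreement = np.mean((fit.raw_propensity > 0.5) == dataset1.exposure)
        assert agreement < 0.95


@pytest.fixture(scope="module")
def boosted(dataset1):
    params = BoostParams(max_trees=400, eval_every=100, seed=0)
    return fit_boosted_cart(dataset1, params), params


class TestBoostedCart:

    def test_chosen_iteration_minimizes_mean_ks(self, boosted):
        fit, _ = boosted
        path = fit.metadata["balance_path"]
        best = path.mean_ks.min()
        chosen_idx = list(path.iterations).index(path.chosen_iteration)
        assert path.mean_ks[chosen_idx] == best
        assert np.all(path.mean_ks >= best)

    def test_deterministic(self, dataset1, boosted):
        fit, params = boosted
        again = fit_boosted_cart(dataset1, params)
        np.testing.assert_array_equal(fit.propensity, again.propensity)
        assert (fit.metadata["chosen_iteration"]
                == again.metadata["chosen_iteration"])

    def test_empty_grid_rejected(self, dataset1):
        with pytest.raises(ValueError, match="grid"):
            fit_boosted_cart(dataset1, BoostParams(max_trees=50,
                                                   eval_every=100))

    def test_balance_improves_over_unweighted(self, dataset1, boosted):
        from pstrim.propensity import mean_ks_balance
        fit, _ = boosted
        unweighted = mean_ks_balance(dataset1.covariates, dataset1.exposure,
                                     np.full(dataset1.n, 0.5))
        weighted = fit.metadata["balance_path"].mean_ks.min()
        assert weighted < unweighted


def test_dispatch_and_unknown_method(dataset1):
    fit = fit_propensity(dataset1, "logistic")
    assert fit.method == "logistic"
    with pytest.raises(ValueError, match="unknown"):
        fit_propensity(dataset1, "neural_net")


def test_one_group_empty_is_an_error(dataset1):
    ds = SimulatedDataset(covariates=dataset1.covariates,
                          exposure=np.zeros(dataset1.n, dtype=int),
                          outcome=dataset1.outcome,
                          true_propensity=dataset1.true_propensity,
                          seed=0, scenario_id=1)
    with pytest.raises(ValueError, match="non-empty"):
        fit_logistic_main_effects(ds)
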