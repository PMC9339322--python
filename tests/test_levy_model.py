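"""Jump-model simulation, marginal likelihoods, EM, and branch posteriors,
checked against independent enumeration and moment oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal, poisson

from gcjump.errors import EnumerationGuardError, GCJumpError
from gcjump.levy_model import (
    BranchPosteriors,
    JumpConfiguration,
    LevyParams,
    branch_jump_posteriors,
    branch_jump_posteriors_exact,
    fit_levy_em,
    levy_covariance,
    levy_marginal_loglik_exact,
    levy_marginal_loglik_mc,
    profile_alpha,
    simulate_levy,
)
from gcjump.synthetic_data import simulate_yule_tree
from gcjump.trait_models import BMParams, bm_loglik, fit_bm

from conftest import random_binary_tree, star_tree, tip_path_lengths


def brute_force_marginal(tree, traits, params, n_max):
    """Independent oracle: sum Poisson(config) x MVN(config) over the full
    truncated configuration grid with dense covariances."""
    labels = tree.tip_labels()
    x = np.array([traits[l] for l in labels])
    branches = list(tree.branches())
    terms = []
    for counts in itertools.product(range(n_max + 1), repeat=len(branches)):
        cfg = np.zeros(tree.n_nodes, dtype=np.int64)
        cfg[branches] = counts
        w = tree.blen + params.alpha * cfg
        w[0] = 0.0
        V = params.sigma2_0 * tip_path_lengths(tree, w)
        lp = sum(
            poisson.logpmf(c, params.lam * tree.blen[b])
            for b, c in zip(branches, counts)
        )
        terms.append(
            lp
            + multivariate_normal.logpdf(
                x, mean=np.full(x.size, params.x0), cov=V
            )
        )
    m = max(terms)
    return m + np.log(np.sum(np.exp(np.array(terms) - m)))


def brute_force_posteriors(tree, traits, params, n_max):
    labels = tree.tip_labels()
    x = np.array([traits[l] for l in labels])
    branches = list(tree.branches())
    num = np.zeros(tree.n_nodes)
    den = 0.0
    for counts in itertools.product(range(n_max + 1), repeat=len(branches)):
        cfg = np.zeros(tree.n_nodes, dtype=np.int64)
        cfg[branches] = counts
        w = tree.blen + params.alpha * cfg
        w[0] = 0.0
        V = params.sigma2_0 * tip_path_lengths(tree, w)
        lp = sum(
            poisson.logpmf(c, params.lam * tree.blen[b])
            for b, c in zip(branches, counts)
        )
        weight = np.exp(
            lp
            + multivariate_normal.logpdf(x, mean=np.full(x.size, params.x0), cov=V)
        )
        den += weight
        num[cfg >= 1] += weight
    return num / den


class TestLevyCovariance:
    def test_zero_config_is_brownian_matrix(self, three_tip_tree):
        cfg = JumpConfiguration(three_tip_tree, np.zeros(5, dtype=int))
        np.testing.assert_allclose(
            levy_covariance(three_tip_tree, cfg, alpha=4.0),
            tip_path_lengths(three_tip_tree),
        )

    def test_stem_jump_adds_alpha_to_cherry_block(self, three_tip_tree):
        counts = np.zeros(5, dtype=int)
        counts[1] = 1  # stem of the (A,B) cherry
        cfg = JumpConfiguration(three_tip_tree, counts)
        V0 = tip_path_lengths(three_tip_tree)
        V = levy_covariance(three_tip_tree, cfg, alpha=4.0)
        D = V - V0
        labels = three_tip_tree.tip_labels()
        ia, ib = labels.index("A"), labels.index("B")
        ic = labels.index("C")
        assert D[ia, ia] == D[ib, ib] == D[ia, ib] == 4.0
        assert D[ic, ic] == 0.0 and D[ia, ic] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_config_matches_path_walk(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(6, rng)
        counts = np.zeros(tree.n_nodes, dtype=int)
        counts[1:] = rng.integers(0, 3, tree.n_nodes - 1)
        cfg = JumpConfiguration(tree, counts)
        alpha = 1.5
        w = tree.blen + alpha * counts
        w[0] = 0.0
        np.testing.assert_allclose(
            levy_covariance(tree, cfg, alpha), tip_path_lengths(tree, w)
        )


class TestSimulate:
    def test_degenerate_limit_pins_tips_at_root_state(self, three_tip_tree):
        params = LevyParams(1e-12, 0.0, 1.0, 43.0)
        traits, cfg = simulate_levy(three_tip_tree, params, seed=0)
        assert all(abs(v - 43.0) < 1e-5 for v in traits.values())
        assert cfg.total_jumps == 0

    def test_star_tree_variance_decomposition(self):
        # Var(tip) = sigma2_0 * t * (1 + lam * alpha) on a unit-depth star;
        # tip values are a heavy-tailed mixture, so average the sample
        # variance over a few replicates to tame the variance of s^2
        t = star_tree(2000, depth=1.0)
        params = LevyParams(1.0, 1.0, 4.0, 0.0)
        vs = [
            np.var(list(simulate_levy(t, params, seed=s)[0].values()))
            for s in (123, 124, 125)
        ]
        assert np.mean(vs) == pytest.approx(5.0, rel=0.05)

    def test_same_seed_reproduces(self, three_tip_tree):
        params = LevyParams(1.0, 2.0, 1.0, 50.0)
        t1, c1 = simulate_levy(three_tip_tree, params, seed=9)
        t2, c2 = simulate_levy(three_tip_tree, params, seed=9)
        assert t1 == t2
        np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_reflection_confines_traits(self):
        tree = simulate_yule_tree(100, seed=4, mean_tip_depth=3.0)
        params = LevyParams(50.0, 2.0, 2.0, 50.0)
        traits, _ = simulate_levy(tree, params, seed=5, gc_bounds=(25.0, 75.0))
        vals = np.array(list(traits.values()))
        assert vals.min() >= 25.0 and vals.max() <= 75.0


class TestMarginalLoglik:
    def test_no_jumps_reduces_to_brownian(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tree = random_binary_tree(int(rng.integers(3, 8)), rng)
            x0 = 50.0
            traits = dict(
                zip(tree.tip_labels(), rng.normal(x0, 2, tree.n_tips))
            )
            params = LevyParams(1.3, 0.0, 2.0, x0)
            ll_levy = levy_marginal_loglik_exact(tree, traits, params)
            ll_bm = bm_loglik(tree, traits, BMParams(1.3, x0))
            assert ll_levy == pytest.approx(ll_bm, abs=1e-9)

    def test_truncation_is_monotone(self, three_tip_tree):
        traits = {"A": 45.0, "B": 55.0, "C": 70.0}
        params = LevyParams(1.0, 0.5, 2.0, 50.0)
        lls = [
            levy_marginal_loglik_exact(three_tip_tree, traits, params, n_max=n)
            for n in (0, 1, 2, 3, 4)
        ]
        assert np.all(np.diff(lls) >= -1e-12)

    def test_matches_independent_enumeration(self, three_tip_tree):
        traits = {"A": 45.0, "B": 55.0, "C": 70.0}
        params = LevyParams(1.0, 0.5, 2.0, 50.0)
        oracle = brute_force_marginal(three_tip_tree, traits, params, n_max=4)
        ours = levy_marginal_loglik_exact(three_tip_tree, traits, params, n_max=4)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_enumeration_guard_trips(self):
        tree = simulate_yule_tree(40, seed=0)
        traits, _ = simulate_levy(tree, LevyParams(1.0, 1.0, 1.0, 50.0), seed=1)
        with pytest.raises(EnumerationGuardError):
            levy_marginal_loglik_exact(
                tree, traits, LevyParams(1.0, 1.0, 1.0, 50.0)
            )

    def test_mc_reduces_to_bm_with_zero_rate(self, three_tip_tree):
        traits = {"A": 45.0, "B": 55.0, "C": 70.0}
        params = LevyParams(1.0, 0.0, 2.0, 50.0)
        est, se = levy_marginal_loglik_mc(three_tip_tree, traits, params, 200, 0)
        assert se == 0.0
        assert est == pytest.approx(bm_loglik(three_tip_tree, traits, BMParams(1.0, 50.0)))

    def test_mc_covers_exact_value(self, three_tip_tree):
        # moderate data: the prior estimator needs workable effective
        # sample sizes for its standard error to be meaningful
        traits = {"A": 48.0, "B": 53.0, "C": 55.0}
        params = LevyParams(1.0, 0.5, 2.0, 50.0)
        exact = levy_marginal_loglik_exact(three_tip_tree, traits, params)
        hits = 0
        for rep in range(50):
            est, se = levy_marginal_loglik_mc(
                three_tip_tree, traits, params, 2000, seed=rep
            )
            if abs(est - exact) <= 3 * se:
                hits += 1
        assert hits >= 45  # >= 90% coverage at 3 standard errors

    def test_mc_standard_error_scaling(self, three_tip_tree):
        traits = {"A": 48.0, "B": 53.0, "C": 55.0}
        params = LevyParams(1.0, 0.5, 2.0, 50.0)
        se_small = np.mean(
            [levy_marginal_loglik_mc(three_tip_tree, traits, params, 2000, s)[1]
             for s in range(20)]
        )
        se_big = np.mean(
            [levy_marginal_loglik_mc(three_tip_tree, traits, params, 4000, s)[1]
             for s in range(20)]
        )
        assert se_big / se_small == pytest.approx(1 / np.sqrt(2), rel=0.2)

    def test_mc_requires_enough_samples(self, three_tip_tree):
        with pytest.raises(GCJumpError):
            levy_marginal_loglik_mc(
                three_tip_tree, {"A": 1, "B": 2, "C": 3},
                LevyParams(1.0, 0.5, 2.0, 2.0), 50, 0,
            )


class TestFitEM:
    def test_same_seed_identical_fits(self):
        tree = simulate_yule_tree(30, seed=2, mean_tip_depth=0.5)
        traits, _ = simulate_levy(tree, LevyParams(50.0, 4.0, 1.0, 50.0), seed=3)
        r1 = fit_levy_em(tree, traits, alpha=1.0, seed=7, em_max_iter=10)
        r2 = fit_levy_em(tree, traits, alpha=1.0, seed=7, em_max_iter=10)
        assert r1.params == r2.params
        assert r1.loglik == r2.loglik

    def test_brownian_data_recovery(self):
        # lam = 0 truth: the rate estimate should stay small (the spurious
        # jump component absorbs only a minor share of variance) and the
        # Brownian rate should be close; the fitted model should not beat
        # BM by more than overfitting noise
        tree = simulate_yule_tree(200, seed=42, jitter_sd=0.3, mean_tip_depth=0.5)
        truth = LevyParams(50.0, 0.0, 1.0, 50.0)
        traits, _ = simulate_levy(tree, truth, seed=43)
        r = fit_levy_em(tree, traits, alpha=1.0, seed=44, em_max_iter=60,
                        n_samples=12, mcmc_steps=6)
        bm, ll_bm = fit_bm(tree, traits)
        # spurious jump variance share: lam*alpha relative to 1
        assert r.params.lam * r.params.alpha < 0.5
        assert r.params.sigma2_0 == pytest.approx(50.0, rel=0.2)
        assert r.loglik - ll_bm < 8.0

    def test_strong_jump_recovery_single_replicate(self):
        truth = LevyParams(1.0, 1.0, 4.0, 50.0)
        tree = simulate_yule_tree(150, seed=61)
        traits, _ = simulate_levy(tree, truth, seed=62)
        r = fit_levy_em(tree, traits, alpha=4.0, seed=63, em_max_iter=50,
                        n_samples=12, mcmc_steps=6)
        assert 0.33 < r.params.lam < 3.0
        assert 0.5 < r.params.sigma2_0 < 2.0

    def test_tiny_tree_rejected(self, three_tip_tree):
        with pytest.raises(GCJumpError):
            fit_levy_em(three_tip_tree, {"A": 1, "B": 2, "C": 3}, alpha=1.0)


class TestProfileAlpha:
    def test_default_grid(self):
        from gcjump.levy_model import DEFAULT_ALPHA_GRID

        assert DEFAULT_ALPHA_GRID == (0.1, 0.25, 0.5, 1.0, 2.0, 4.0)

    def test_single_value_grid(self):
        tree = simulate_yule_tree(30, seed=2, mean_tip_depth=0.5)
        traits, _ = simulate_levy(tree, LevyParams(50.0, 4.0, 1.0, 50.0), seed=3)
        fit = profile_alpha(tree, traits, alpha_grid=(1.0,), seed=5, em_max_iter=8)
        assert fit.best_alpha == 1.0
        assert set(fit.alpha_grid) == {1.0}

    def test_best_alpha_attains_grid_maximum(self):
        tree = simulate_yule_tree(40, seed=8, mean_tip_depth=0.5)
        traits, _ = simulate_levy(tree, LevyParams(50.0, 4.0, 2.0, 50.0), seed=9)
        fit = profile_alpha(
            tree, traits, alpha_grid=(0.25, 1.0, 4.0), seed=10, em_max_iter=15
        )
        best = max(fit.alpha_grid.values(), key=lambda r: r.loglik)
        assert fit.loglik == best.loglik
        assert fit.params == best.params


class TestBranchPosteriors:
    def test_zero_rate_forbids_jumps(self, three_tip_tree):
        post = branch_jump_posteriors(
            three_tip_tree, {"A": 45.0, "B": 55.0, "C": 70.0},
            LevyParams(1.0, 0.0, 2.0, 50.0), seed=0,
        )
        np.testing.assert_array_equal(post.pp, 0.0)
        assert post.converged

    def test_three_tip_posteriors_match_enumeration(self, three_tip_tree):
        traits = {"A": 45.0, "B": 55.0, "C": 70.0}
        params = LevyParams(1.0, 0.5, 2.0, 50.0)
        oracle = brute_force_posteriors(three_tip_tree, traits, params, n_max=5)
        post = branch_jump_posteriors(
            three_tip_tree, traits, params,
            mcmc_steps=40_000, burn_in=4_000, seed=1,
        )
        np.testing.assert_allclose(
            post.pp[1:], oracle[1:], atol=0.02
        )

    def test_exact_posterior_helper_agrees_with_oracle(self, three_tip_tree):
        traits = {"A": 45.0, "B": 55.0, "C": 70.0}
        params = LevyParams(1.0, 0.5, 2.0, 50.0)
        oracle = brute_force_posteriors(three_tip_tree, traits, params, n_max=6)
        post = branch_jump_posteriors_exact(three_tip_tree, traits, params)
        np.testing.assert_allclose(post.pp[1:], oracle[1:], atol=1e-4)

    def test_planted_jump_attains_top_posterior(self):
        # a single huge planted jump: that branch should dominate the
        # posterior in nearly all replicates
        wins = 0
        for rep in range(10):
            tree = simulate_yule_tree(40, seed=900 + rep, mean_tip_depth=0.5)
            # plant on an internal branch subtending a few tips
            cands = [
                b for b in tree.branches()
                if not tree.is_tip[b] and 3 <= tree.subtree_tips(b).size <= 10
            ]
            b = cands[rep % len(cands)]
            traits, _ = simulate_levy(
                tree, LevyParams(1.0, 0.0, 1.0, 50.0), seed=rep
            )
            shift = 10.0 * np.sqrt(0.5)
            for t_idx in tree.subtree_tips(b):
                traits[tree.labels[t_idx]] += shift
            params = LevyParams(1.0, 0.2, 25.0, 50.0)
            post = branch_jump_posteriors(
                tree, traits, params, mcmc_steps=2000, burn_in=500, seed=rep
            )
            if np.argmax(post.pp) == b:
                wins += 1
        assert wins >= 9

    def test_posterior_monotone_in_planted_magnitude(self):
        tree = simulate_yule_tree(30, seed=77, mean_tip_depth=0.5)
        cands = [
            b for b in tree.branches()
            if not tree.is_tip[b] and 3 <= tree.subtree_tips(b).size <= 8
        ]
        b = cands[0]
        params = LevyParams(1.0, 0.3, 10.0, 50.0)
        medians = []
        for shift in (0.0, 2.0, 8.0):
            pps = []
            for rep in range(5):
                traits, _ = simulate_levy(
                    tree, LevyParams(1.0, 0.0, 1.0, 50.0), seed=1000 + rep
                )
                for t_idx in tree.subtree_tips(b):
                    traits[tree.labels[t_idx]] += shift
                post = branch_jump_posteriors(
                    tree, traits, params, mcmc_steps=1500, burn_in=300,
                    seed=rep,
                )
                pps.append(post.pp[b])
            medians.append(np.median(pps))
        assert medians[0] <= medians[1] <= medians[2]

    def test_posterior_calibration_band(self):
        # empirical-Bayes calibration at the true parameters: among
        # branches with pp in [0.8, 0.9], the fraction truly carrying a
        # jump should be comparable to the posterior statement
        params = LevyParams(50.0, 4.0, 2.0, 50.0)
        n_in_band = 0
        n_true = 0
        for rep in range(25):
            tree = simulate_yule_tree(40, seed=500 + rep, mean_tip_depth=0.5)
            traits, truth = simulate_levy(tree, params, seed=600 + rep)
            post = branch_jump_posteriors(
                tree, traits, params, mcmc_steps=1500, burn_in=300, seed=rep
            )
            for br in tree.branches():
                if 0.8 <= post.pp[br] <= 0.9:
                    n_in_band += 1
                    n_true += int(truth.counts[br] >= 1)
        assert n_in_band >= 10
        assert 0.7 <= n_true / n_in_band <= 1.0

    def test_invalid_step_budget(self, three_tip_tree):
        with pytest.raises(GCJumpError):
            branch_jump_posteriors(
                three_tip_tree, {"A": 1, "B": 2, "C": 3},
                LevyParams(1.0, 1.0, 1.0, 2.0), mcmc_steps=10, burn_in=10,
            )


def test_configuration_container_contracts(three_tip_tree):
    with pytest.raises(GCJumpError):
        JumpConfiguration(three_tip_tree, np.array([1, 0, 0, 0, 0]))  # root jump
    with pytest.raises(GCJumpError):
        JumpConfiguration.from_dict(three_tip_tree, {1: 0, 2: 1})  # missing keys
    cfg = JumpConfiguration.from_dict(three_tip_tree, {1: 0, 2: 1, 3: 0, 4: 2})
    assert cfg.total_jumps == 3
    assert set(cfg.branches_with_jumps()) == {2, 4}
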