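"""Knockoff statistics, thresholds, aggregation, importance measures."""

import numpy as np
import pytest

from reko import (
    KnockoffStatsSet,
    aggregate_select,
    combined_filter,
    gen_features,
    knockoff_stats,
    knockoff_threshold,
    lasso_importance,
    pip_importance,
    standardize,
)

from conftest import exact_pips, threshold_oracle


class TestKnockoffStats:
    def test_pairwise_difference(self):
        imp = np.array([0.5, 0.1, 0.0, 0.2, 0.3, 0.0])
        np.testing.assert_allclose(knockoff_stats(imp), [0.3, -0.2, 0.0])

    def test_antisymmetry_under_label_swap(self, rng):
        imp = rng.uniform(size=12)
        swapped = np.concatenate([imp[6:], imp[:6]])
        np.testing.assert_allclose(
            knockoff_stats(swapped), -knockoff_stats(imp)
        )

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError, match="2p"):
            knockoff_stats(np.ones(5))


class TestThreshold:
    def test_worked_example_both_variants(self):
        W = np.array([5.0, 4.0, 3.0, -1.0, -2.0])
        # ratios at t=1: 2/3, t=2: 1/3, t=3: 0/3 -> T=3 selecting three
        assert knockoff_threshold(W, 0.2, "knockoff") == 3.0
        # plus-variant numerators (0+1)/3, (1+1)/... never reach 0.2
        assert knockoff_threshold(W, 0.2, "knockoff_plus") == np.inf

    def test_all_positive_selects_everything(self, rng):
        W = rng.uniform(0.1, 2.0, size=20)
        t = knockoff_threshold(W, 0.05, "knockoff")
        assert t == W.min()
        assert np.sum(W >= t) == 20

    def test_all_negative_selects_nothing(self, rng):
        W = -rng.uniform(0.1, 2.0, size=20)
        assert knockoff_threshold(W, 0.5, "knockoff") == np.inf

    def test_all_zero_warns_and_returns_inf(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert knockoff_threshold(np.zeros(6), 0.1) == np.inf

    @pytest.mark.parametrize("variant", ["knockoff", "knockoff_plus"])
    def test_matches_brute_force_oracle(self, variant):
        # the acceptance bar: 1000 random statistic vectors
        r = np.random.default_rng(99)
        for _ in range(1000):
            p = int(r.integers(2, 40))
            W = np.round(r.standard_normal(p), 3)
            q = float(r.uniform(0.02, 0.5))
            assert knockoff_threshold(W, q, variant) == threshold_oracle(W, q, variant)


class TestAggregation:
    def test_M1_reduces_to_single_copy_filter(self, rng):
        W = rng.standard_normal(30)
        stats = KnockoffStatsSet(W=W[None, :])
        sel = aggregate_select(stats, 0.2)
        t = knockoff_threshold(W, 0.2)
        np.testing.assert_array_equal(sel.selected, np.flatnonzero(W >= t))
        assert sel.threshold == t
        assert not sel.aggregated

    def test_duplicated_copies_leave_selection_unchanged(self, rng):
        W = rng.standard_normal(30)
        single = aggregate_select(KnockoffStatsSet(W=W[None, :]), 0.2)
        stacked = aggregate_select(KnockoffStatsSet(W=np.tile(W, (7, 1))), 0.2)
        np.testing.assert_array_equal(single.selected, stacked.selected)
        assert single.threshold == stacked.threshold

    def test_W_bar_and_W_cat_consistency(self, rng):
        W = rng.standard_normal((4, 9))
        stats = KnockoffStatsSet(W=W)
        np.testing.assert_allclose(stats.W_bar, W.mean(axis=0))
        assert stats.W_cat.size == 36

    def test_negated_statistics_select_nothing(self, rng):
        W = rng.uniform(0.5, 2.0, size=(3, 15))
        sel = aggregate_select(KnockoffStatsSet(W=-W), 0.3)
        assert sel.selected.size == 0 and sel.threshold == np.inf

    def test_null_sign_flip_counting_identity(self, rng):
        # flipping signs of null statistics swaps the two counts at t
        W = rng.standard_normal(200)
        t = 0.5
        flipped = W * rng.choice([-1, 1], size=200)
        for vec in (W, flipped):
            neg = np.sum(vec <= -t)
            pos = np.sum(vec >= t)
            # under exchangeability both counts estimate the same null tail
            assert abs(neg - pos) <= 4 * np.sqrt(max(neg + pos, 1))


class TestCombinedFilter:
    def _sel(self, idx, p=10, q=0.1):
        from reko.filter import SelectionResult

        return SelectionResult(
            threshold=1.0, selected=np.array(idx), q=q, variant="knockoff",
            n_features=p,
        )

    def test_intersection(self):
        out = combined_filter(self._sel([1, 2, 3]), self._sel([2, 3, 4]))
        np.testing.assert_array_equal(out.selected, [2, 3])

    def test_empty_and_identical(self):
        assert combined_filter(self._sel([1, 2]), self._sel([])).selected.size == 0
        out = combined_filter(self._sel([1, 2]), self._sel([1, 2]))
        np.testing.assert_array_equal(out.selected, [1, 2])

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            combined_filter(self._sel([1], p=10), self._sel([1], p=12))


class TestLassoImportance:
    def test_null_sign_symmetry(self):
        # independent phenotype: positive and negative W roughly balanced
        # (fixed small penalty so the null fit keeps many nonzero terms)
        X = gen_features(300, 40, "independent", seed=21)
        Xt = gen_features(300, 40, "independent", seed=22).values
        pos = tot = 0
        for seed in range(12):
            y = np.random.default_rng(500 + seed).standard_normal(300)
            W = knockoff_stats(
                lasso_importance(X.values, Xt, y, seed=seed, alpha=0.05)
            )
            nz = W[W != 0]
            pos += int((nz > 0).sum())
            tot += nz.size
        assert tot >= 100
        assert 0.3 <= pos / tot <= 0.7

    def test_strong_causal_feature_wins(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(3000 + seed)
            X = gen_features(200, 15, "independent", seed=700 + seed)
            Xt = gen_features(200, 15, "independent", seed=800 + seed).values
            y = 5.0 * X.values[:, 4] + r.standard_normal(200)
            W = knockoff_stats(lasso_importance(X.values, Xt, y, seed=seed))
            if np.argmax(W) == 4 and W[4] > 0:
                hits += 1
        assert hits >= 36  # ~95% with Monte-Carlo slack

    def test_self_knockoff_kills_all_statistics(self, rng):
        X = gen_features(150, 10, "ar1", seed=31, rho=0.5)
        y = X.values[:, 0] * 2 + rng.standard_normal(150)
        W = knockoff_stats(lasso_importance(X.values, X.values.copy(), y, seed=1))
        assert np.abs(W).max() <= 0.35  # identical columns share the credit

    def test_zero_variance_phenotype_rejected(self, rng):
        X = gen_features(50, 5, "independent", seed=41)
        with pytest.raises(ValueError, match="variance"):
            lasso_importance(X.values, X.values, np.ones(50))


class TestPipImportance:
    def test_matches_exact_enumeration(self, rng):
        # small instance: Gibbs PIPs vs exhaustive posterior enumeration
        n = 150
        base = rng.standard_normal(n)
        dups = np.column_stack(
            [base + 1e-3 * rng.standard_normal(n) for _ in range(4)]
        )
        X = standardize(np.hstack([dups, rng.standard_normal((n, 1))]))
        y = 3.0 * X.values[:, 0] + 2.0 * rng.standard_normal(n)
        Xt = standardize(np.random.default_rng(11).standard_normal((n, 5))).values
        pi0, v = 0.2, 1.0
        ex = exact_pips(np.hstack([X.values, Xt]), y, pi0, v)
        gp = pip_importance(
            X.values, Xt, y,
            mcmc={"iters": 4000, "burnin": 1000, "pi0": pi0, "slab_var": v},
            seed=5,
        )
        assert np.abs(gp - ex).max() <= 0.08

    def test_near_duplicates_share_credit(self, rng):
        # four indistinguishable proxies of one causal signal split the
        # posterior roughly evenly (model averaging), none dominating
        n = 150
        base = rng.standard_normal(n)
        dups = np.column_stack(
            [base + 1e-3 * rng.standard_normal(n) for _ in range(4)]
        )
        X = standardize(np.hstack([dups, rng.standard_normal((n, 1))]))
        y = 3.0 * X.values[:, 0] + 2.0 * rng.standard_normal(n)
        Xt = standardize(np.random.default_rng(11).standard_normal((n, 5))).values
        gp = pip_importance(
            X.values, Xt, y,
            mcmc={"iters": 4000, "burnin": 1000, "pi0": 0.2}, seed=6,
        )
        assert np.all(gp[:4] > 0.1) and np.all(gp[:4] < 0.7)
        assert np.ptp(gp[:4]) <= 0.25
        assert gp[4:].max() < 0.15

    def test_null_phenotype_stays_uncommitted(self, rng):
        X = gen_features(150, 10, "independent", seed=51)
        Xt = gen_features(150, 10, "independent", seed=52).values
        y = rng.standard_normal(150)
        gp = pip_importance(X.values, Xt, y,
                            mcmc={"iters": 1500, "burnin": 500}, seed=7)
        assert gp.max() < 0.5
        assert gp.mean() < 3 * (1 / 10)

    def test_strong_signal_high_pip(self, rng):
        X = gen_features(150, 10, "independent", seed=61)
        Xt = gen_features(150, 10, "independent", seed=62).values
        y = 4.0 * X.values[:, 3] + rng.standard_normal(150)
        gp = pip_importance(X.values, Xt, y,
                            mcmc={"iters": 1500, "burnin": 500}, seed=8)
        assert gp[3] > 0.9

    def test_deterministic_given_seed(self, rng):
        X = gen_features(80, 6, "independent", seed=71)
        Xt = gen_features(80, 6, "independent", seed=72).values
        y = X.values[:, 0] + rng.standard_normal(80)
        kw = dict(mcmc={"iters": 400, "burnin": 100})
        a = pip_importance(X.values, Xt, y, seed=9, **kw)
        b = pip_importance(X.values, Xt, y, seed=9, **kw)
        np.testing.assert_array_equal(a, b)

    def test_bad_mcmc_settings_rejected(self, rng):
        X = gen_features(50, 4, "independent", seed=81)
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="burnin"):
            pip_importance(X.values, X.values, y,
                           mcmc={"iters": 100, "burnin": 100})
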