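import math

import numpy as np
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import roc_auc_score

from knmbp.evaluation import (
    cv_folds,
    fisher_top_bottom,
    grid_search,
    marginal_summary,
    mean_seed_auc,
    minmax_normalize,
    roc_auc,
)


def fisher_two_sided_enumeration(table):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(k, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestCVFolds:
    def test_folds_partition_all_pairs(self):
        y = (np.random.default_rng(0).random((8, 6)) < 0.3).astype(float)
        plan = cv_folds(y, "pairs", k=5, seed=3)
        combined = np.sort(np.concatenate(plan.folds))
        np.testing.assert_array_equal(combined, np.arange(48))

    def test_stratified_counts(self):
        y = np.zeros(100)
        y[:10] = 1
        y = y.reshape(10, 10)
        plan = cv_folds(y, "pairs", k=5, seed=0)
        for fold in plan.folds:
            labels = y.ravel()[fold]
            assert labels.sum() == 2
            assert len(labels) == 20

    def test_same_seed_reproduces_folds(self):
        y = (np.random.default_rng(1).random((7, 9)) < 0.2).astype(float)
        p1 = cv_folds(y, "mirnas", k=3, seed=11)
        p2 = cv_folds(y, "mirnas", k=3, seed=11)
        for f1, f2 in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(f1, f2)

    @pytest.mark.parametrize("mode,axis_len", [("mirnas", 10), ("diseases", 8)])
    def test_entity_modes_partition_axis(self, mode, axis_len):
        y = np.zeros((10, 8))
        plan = cv_folds(y, mode, k=4, seed=2)
        combined = np.sort(np.concatenate(plan.folds))
        np.testing.assert_array_equal(combined, np.arange(axis_len))
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_train_mask_masks_only_test_units(self):
        y = np.zeros((6, 4))
        plan = cv_folds(y, "diseases", k=2, seed=0)
        mask = plan.train_mask(0)
        assert (~mask).all(axis=0).sum() == len(plan.folds[0])

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            cv_folds(np.zeros((3, 5)), "mirnas", k=5, seed=0)


class TestMinMaxNormalize:
    def test_examples(self):
        np.testing.assert_allclose(
            minmax_normalize(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0]
        )
        np.testing.assert_allclose(
            minmax_normalize(np.array([-1.0, 0.0, 3.0])), [0.0, 0.25, 1.0]
        )

    def test_already_normalized_unchanged(self):
        x = np.array([0.0, 0.3, 1.0])
        np.testing.assert_allclose(minmax_normalize(x), x)

    def test_constant_scores_warn_and_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(np.full(4, 2.5))
        np.testing.assert_array_equal(out, 0.0)


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        assert roc_auc(scores, labels).auc == pytest.approx(1.0, abs=1e-12)

    def test_grid_auc_matches_rank_statistic(self, rng):
        for _ in range(5):
            scores = rng.random(200)
            labels = (rng.random(200) < 0.3).astype(int)
            res = roc_auc(scores, labels)
            assert abs(res.auc - roc_auc_score(labels, scores)) <= 1e-3

    def test_small_fixture_rank_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        res = roc_auc(scores, labels)
        assert abs(res.auc - roc_auc_score(labels, scores)) <= 1e-3

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.random(2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_rates_monotone_in_threshold(self, rng):
        scores = rng.random(100)
        labels = (rng.random(100) < 0.4).astype(int)
        res = roc_auc(scores, labels)
        assert (np.diff(res.mean_tpr) <= 1e-12).all()
        assert (np.diff(res.mean_fpr) <= 1e-12).all()

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(150)
        labels = (rng.random(150) < 0.3).astype(int)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores), labels).auc
        assert abs(a - b) <= 1e-3

    def test_fold_averaging(self, rng):
        scores = [rng.random(50), rng.random(60)]
        labels = [(rng.random(50) < 0.4).astype(int), (rng.random(60) < 0.4).astype(int)]
        res = roc_auc(scores, labels)
        per_fold = [roc_auc(s, l) for s, l in zip(scores, labels)]
        np.testing.assert_allclose(
            res.mean_tpr, np.mean([r.mean_tpr for r in per_fold], axis=0), atol=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_mean_seed_auc(self):
        assert mean_seed_auc([0.8, 0.9]) == pytest.approx(0.85)


class TestFisherTopBottom:
    def _ranked(self, top_conf, bottom_conf, group_size=20):
        """Candidate list whose top/bottom groups have the given confirmed counts."""
        top = [f"t{i}" for i in range(group_size)]
        bottom = [f"b{i}" for i in range(group_size)]
        confirmed = set(top[:top_conf]) | set(bottom[:bottom_conf])
        return top + bottom, confirmed

    def test_printed_colon_neoplasms_table(self):
        ranked, confirmed = self._ranked(18, 2)
        table, p = fisher_top_bottom(ranked, confirmed)
        np.testing.assert_array_equal(table, [[18, 2], [2, 18]])
        assert p == pytest.approx(5.2959e-7, rel=5e-5)

    def test_fully_separated_table(self):
        ranked, confirmed = self._ranked(20, 0)
        table, p = fisher_top_bottom(ranked, confirmed)
        np.testing.assert_array_equal(table, [[20, 0], [0, 20]])
        assert p == pytest.approx(2 / math.comb(40, 20), rel=1e-9)
        assert p == pytest.approx(1.4509e-11, rel=5e-5)

    def test_equal_confirmation_gives_p_one(self):
        ranked, confirmed = self._ranked(5, 5)
        _, p = fisher_top_bottom(ranked, confirmed)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            gs = int(rng.integers(3, 21))
            ranked, confirmed = self._ranked(
                int(rng.integers(0, gs + 1)), int(rng.integers(0, gs + 1)), gs
            )
            table, p = fisher_top_bottom(ranked, confirmed, group_size=gs)
            assert p == pytest.approx(fisher_two_sided_enumeration(table), rel=1e-8)

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            fisher_top_bottom([f"c{i}" for i in range(30)], set(), group_size=20)


class TestGridSearch:
    def test_singleton_grid(self):
        best, table = grid_search({"a": [2]}, lambda p: 0.7)
        assert best == {"a": 2}
        assert len(table) == 1

    def test_table_covers_whole_grid_and_argmax(self):
        grid = {"pn": [0.1, 0.5], "lam": [0.25, 1.0, 4.0]}
        best, table = grid_search(grid, lambda p: p["pn"] + 1 / p["lam"])
        assert len(table) == 6
        assert best == {"pn": 0.5, "lam": 0.25}

    def test_marginal_summary_matches_brute_force(self):
        grid = {"pn": [0.1, 0.5], "lam": [0.25, 1.0], "mu": [1, 2, 4]}
        _, table = grid_search(grid, lambda p: p["pn"] * p["lam"] + 0.01 * p["mu"])
        summary = marginal_summary(table, ["pn", "lam"])
        for _, row in summary.iterrows():
            cell = table[(table["pn"] == row["pn"]) & (table["lam"] == row["lam"])]["auc"]
            assert row["max"] == pytest.approx(cell.max())
            assert row["mean"] == pytest.approx(cell.mean())
            assert row["min"] == pytest.approx(cell.min())
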