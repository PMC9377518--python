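"""LOOCV SVM with nested feature selection: ranking, training, inference.

Independent oracles: the squared pooled t for F scores, a generic
quadratic-programming solve of the SVM dual for the weights, and exhaustive
pair counting for the AUC.
"""

import numpy as np
import pytest
from scipy import optimize

import fcmvpa as f
from fcmvpa.mvpa import HC_LABEL, OSA_LABEL, n_selected


def qp_svm(x, y, C=1.0):
    """Solve the soft-margin SVM dual with a general-purpose QP solver."""
    n = x.shape[0]
    q = (y[:, None] * x) @ (y[:, None] * x).T

    def objective(a):
        return 0.5 * a @ q @ a - a.sum()

    def grad(a):
        return q @ a - np.ones(n)

    res = optimize.minimize(
        objective,
        np.zeros(n),
        jac=grad,
        bounds=[(0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y.astype(float)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    a = res.x
    w = (a * y) @ x
    margin = (a > 1e-6) & (a < C - 1e-6)
    b = float(np.mean(y[margin] - x[margin] @ w))
    return w, b


class TestFScoreRanking:
    def test_equal_group_means_zero_f(self):
        x = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([1, 1, -1, -1])
        fscores, _ = f.f_score_rank(x, y)
        assert fscores[0] == 0.0

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((12, 40))
        y = np.array([1] * 5 + [-1] * 7)
        fscores, _ = f.f_score_rank(x, y)
        t, _, _ = f.two_sample_t(x[y == 1], x[y == -1])
        assert np.allclose(fscores, t**2, atol=1e-10)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 20))
        y = np.array([1] * 5 + [-1] * 5)
        perm = rng.permutation(10)
        f1, _ = f.f_score_rank(x, y)
        f2, _ = f.f_score_rank(x[perm], y[perm])
        assert np.allclose(f1, f2)

    def test_zero_within_variance_ranks_first(self):
        x = np.column_stack([[1.0, 1, 2, 2], [0.1, -0.2, 0.3, 0.0]])
        y = np.array([1, 1, -1, -1])
        fscores, order = f.f_score_rank(x, y)
        assert np.isinf(fscores[0])
        assert order[0] == 0

    def test_ties_break_by_ascending_index(self):
        x = np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 3))
        y = np.array([1, 1, -1, -1])
        _, order = f.f_score_rank(x, y)
        assert order.tolist() == [0, 1, 2]


class TestSelection:
    @pytest.mark.parametrize(
        "pct,e,expected", [(10, 4005, 400), (100, 4005, 4005), (10, 10, 1), (30, 4005, 1201)]
    )
    def test_floor_counts(self, pct, e, expected):
        assert n_selected(pct, e) == expected
        assert f.select_top_fraction(np.arange(e), pct, e).size == expected

    def test_zero_selection_rejected(self):
        with pytest.raises(ValueError):
            n_selected(10, 5)


class TestLinearSVM:
    def test_symmetric_separable_toy(self):
        x = np.array([[1.0, 1], [2, 2], [-1, -1], [-2, -2]])
        y = np.array([1, 1, -1, -1])
        w, b = f.train_linear_svm(x, y, C=10.0)
        assert np.all(np.sign(x @ w + b) == y)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_matches_quadratic_programming_oracle(self):
        rng = np.random.default_rng(3)
        for C in (0.5, 1.0):
            x = rng.standard_normal((10, 4)) + np.array([1.0, 0, 0, 0]) * rng.choice(
                [1, -1], size=(10, 1)
            )
            y = np.array([1] * 5 + [-1] * 5)
            w, b = f.train_linear_svm(x, y, C=C, tol=1e-8)
            w_qp, b_qp = qp_svm(x, y, C=C)
            assert np.allclose(w, w_qp, atol=1e-4)
            assert b == pytest.approx(b_qp, abs=1e-3)

    def test_matches_public_estimator(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.standard_normal((9, 6))
            y = rng.choice([1, -1], size=9)
            if np.unique(y).size < 2:
                continue
            w, b = f.train_linear_svm(x, y, C=1.0)
            clf = SVC(kernel="linear", C=1.0).fit(x, y)
            assert np.allclose(w, clf.coef_[0], atol=1e-10)
            assert b == pytest.approx(float(clf.intercept_[0]), abs=1e-10)

    def test_duplicated_feature_splits_weight(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((12, 1)) + np.array([2.0]) * np.repeat([1, -1], 6)[:, None]
        x = np.hstack([base, base])
        y = np.repeat([1, -1], 6)
        w, _ = f.train_linear_svm(x, y, C=1.0)
        assert w[0] == pytest.approx(w[1], abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            f.train_linear_svm(np.ones((4, 2)), np.ones(4))

    def test_scaling_invariance_of_boundary_at_large_c(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((10, 3)) + np.array([3.0, 0, 0]) * np.repeat([1, -1], 5)[:, None]
        y = np.repeat([1, -1], 5)
        w1, b1 = f.train_linear_svm(x, y, C=1e6)
        w2, b2 = f.train_linear_svm(2 * x, y, C=1e6)
        # same boundary: w2 = w1/2, b unchanged (hard-margin geometry)
        assert np.allclose(w2, w1 / 2, atol=1e-4)
        assert b2 == pytest.approx(b1, abs=1e-4)


class TestLOOCV:
    def test_perfect_separation_all_percentages(self, small_cohort):
        res = f.loocv_classify(small_cohort["x"], small_cohort["y"], percentages=(10, 50, 100))
        assert np.allclose(res.accuracy, 1.0)
        assert np.allclose(res.sensitivity, 1.0)
        assert np.allclose(res.specificity, 1.0)
        assert res.best_percentage == 10  # ties resolve to the smallest grid point

    def test_chance_level_on_random_labels(self):
        rng = np.random.default_rng(7)
        accs = []
        for trial in range(20):
            x = rng.standard_normal((12, 30))
            y = np.repeat([1, -1], 6)
            accs.append(f.loocv_classify(x, y, percentages=(50, 100)).accuracy.mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.12)

    def test_feature_selection_sees_training_folds_only(self):
        # feature 1 separates the groups perfectly except for subject 0, whose
        # outlying value wrecks its full-data F score; feature 0 carries a
        # modest consistent difference.  A leaky (full-data) ranking therefore
        # prefers feature 0, but the fold holding out subject 0 must rank
        # feature 1 first because its training data are perfectly separated.
        x = np.zeros((6, 2))
        x[:, 0] = [0.5, 0.6, 0.4, -0.5, -0.4, -0.6]
        x[:, 1] = [-5.0, 1.0, 1.1, -1.0, -0.9, -1.1]
        y = np.array([1, 1, 1, -1, -1, -1])
        leaky_order = f.f_score_rank(x, y)[1]
        assert leaky_order[0] == 0  # sanity: full-data ranking prefers feature 0
        res = f.loocv_classify(x, y, percentages=(50,))
        fold0 = res.folds[0]
        assert fold0.selected[50].tolist() == [1]

    def test_deterministic(self, small_cohort):
        r1 = f.run_mvpa(small_cohort["x"], small_cohort["y"], percentages=(10, 100), seed=3)
        r2 = f.run_mvpa(small_cohort["x"], small_cohort["y"], percentages=(10, 100), seed=3)
        assert np.array_equal(r1.decision_values, r2.decision_values)
        assert np.array_equal(r1.selected.weights, r2.selected.weights)

    def test_minimum_cohort_enforced(self):
        with pytest.raises(ValueError):
            f.loocv_classify(np.ones((3, 4)), np.array([1, -1, 1]), percentages=(100,))


class TestROC:
    def test_perfect_ordering(self):
        y = np.array([HC_LABEL] * 3 + [OSA_LABEL] * 3)
        d = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])  # decision oriented to HC
        _, _, auc = f.roc_auc(d, y)
        assert auc == 1.0

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        y = np.array([HC_LABEL, OSA_LABEL, HC_LABEL, OSA_LABEL, OSA_LABEL, HC_LABEL])
        d = rng.standard_normal(6)
        _, _, auc = f.roc_auc(d, y)
        pat = -d[y == OSA_LABEL]
        ctl = -d[y == HC_LABEL]
        wins = sum((p > c) + 0.5 * (p == c) for p in pat for c in ctl)
        assert auc == pytest.approx(wins / (len(pat) * len(ctl)), abs=1e-12)

    def test_chance_level_for_independent_scores(self):
        rng = np.random.default_rng(9)
        y = np.repeat([HC_LABEL, OSA_LABEL], 300)
        d = rng.standard_normal(600)
        _, _, auc = f.roc_auc(d, y)
        assert auc == pytest.approx(0.5, abs=0.07)


class TestAggregation:
    def test_identical_folds_give_exact_grid_size(self, small_cohort):
        x = small_cohort["x"].copy()
        # make one block of features overwhelmingly dominant so selection is stable
        x[:, :4] += np.repeat([5.0, -5.0], 8)[:, None]
        res = f.loocv_classify(x, small_cohort["y"], percentages=(10,))
        sel = f.aggregate_selected_edges(res.folds, 10, x.shape[1])
        if all(
            np.array_equal(fold.selected[10], res.folds[0].selected[10])
            for fold in res.folds
        ):
            assert sel.edges.size == n_selected(10, x.shape[1])
        assert sel.edges.size >= n_selected(10, x.shape[1])

    def test_frequency_and_weight_bookkeeping(self):
        folds = [
            f.mvpa.FoldResult(
                test_index=k, true_label=1,
                selected={50: np.array([0, 1])} if k == 0 else {50: np.array([1, 2])},
                weights={50: np.array([0.5, 1.0])} if k == 0 else {50: np.array([2.0, -1.0])},
                bias={50: 0.0}, decision={50: 0.0}, predicted={50: 1},
            )
            for k in range(2)
        ]
        sel = f.aggregate_selected_edges(folds, 50, 4)
        assert sel.edges.tolist() == [0, 1, 2]
        assert sel.weights == pytest.approx([0.5, 1.5, -1.0])
        assert sel.frequency == pytest.approx([0.5, 1.0, 0.5])
        assert sel.positive.tolist() == [0, 1]
        assert sel.negative.tolist() == [2]


class TestPermutationTest:
    def test_separable_data_hits_p_floor(self, small_cohort):
        null_max, fwe_p = f.permutation_test(
            small_cohort["x"], small_cohort["y"], percentages=(10, 100),
            n_perm=100, seed=1,
        )
        assert np.all(fwe_p == 1 / 100)

    def test_null_max_dominates_each_grid_point(self, null_cohort):
        null_max, _, null_grid = f.permutation_test(
            null_cohort["x"], null_cohort["y"], percentages=(50, 100),
            n_perm=100, seed=2, return_full=True,
        )
        assert np.all(null_max[:, None] >= null_grid)
        assert np.array_equal(null_max, null_grid.max(axis=1))

    def test_global_mode_runs_and_differs(self, null_cohort):
        nm_w, _ = f.permutation_test(
            null_cohort["x"], null_cohort["y"], percentages=(100,), n_perm=100, seed=3
        )
        nm_g, _ = f.permutation_test(
            null_cohort["x"], null_cohort["y"], percentages=(100,), n_perm=100, seed=3,
            mode="global",
        )
        assert nm_w.shape == nm_g.shape == (100,)
        assert not np.array_equal(nm_w, nm_g)

    def test_run_mvpa_attaches_inference(self, small_cohort):
        res = f.run_mvpa(
            small_cohort["x"], small_cohort["y"], percentages=(10, 100),
            n_perm=100, seed=5,
        )
        assert res.fwe_p is not None and res.fwe_p.shape == (2,)
        assert res.null_max.shape == (100,)
        assert res.auc == 1.0
        assert res.final_accuracy == 1.0
        assert res.fwe_p[0] == 1 / 100

    def test_implanted_edges_enriched_in_selection(self, small_cohort):
        res = f.run_mvpa(small_cohort["x"], small_cohort["y"], percentages=(10,))
        sel = set(res.selected.edges.tolist())
        implanted = set(int(e) for e in small_cohort["spec"].effect_edges)
        overlap = len(sel & implanted)
        assert overlap >= 8  # 10 implanted edges, near-complete recovery expected
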