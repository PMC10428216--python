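"""One-rule classifier: exhaustive-oracle equality, evaluation, ablation, lasso."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from kinoflex.alignment import FluctuationMatrix
from kinoflex.stump import (
    DecisionStumpClassifier,
    ablation_cascade,
    balanced_accuracy,
    fit_stump,
    lasso_select,
    resampled_evaluation,
)
from kinoflex.synthetic import PanelSpec, gen_fluctuation_panel


def brute_force_stump(X, y):
    """Independent exhaustive oracle: double loop over columns and midpoints.

    Scans columns in ascending order and thresholds in ascending order,
    keeping the first strictly-better impurity — i.e. ties break toward the
    lowest column, then the lowest threshold, matching the declared rule.
    """
    n, p = X.shape
    best = (np.inf, None, None, None)
    for j in range(p):
        vals = np.sort(np.unique(X[:, j]))
        for a, b in zip(vals, vals[1:]):
            thr = 0.5 * (a + b)
            below = X[:, j] <= thr
            nb, na = below.sum(), n - below.sum()
            ab, aa = y[below].sum(), y[~below].sum()
            gini_b = 1.0 - (ab / nb) ** 2 - ((nb - ab) / nb) ** 2
            gini_a = 1.0 - (aa / na) ** 2 - ((na - aa) / na) ** 2
            imp = (nb * gini_b + na * gini_a) / n
            if imp < best[0]:
                orient = "active" if ab / nb >= aa / na else "inactive"
                best = (imp, j, thr, orient)
    return best


def random_instance(rng, max_rows=15, max_cols=10):
    n = rng.integers(4, max_rows + 1)
    p = rng.integers(1, max_cols + 1)
    # duplicate-heavy values exercise the distinct-midpoint rule and ties
    X = np.round(rng.uniform(0, 2, (n, p)), 1)
    y = rng.integers(0, 2, n)
    while y.min() == y.max():
        y = rng.integers(0, 2, n)
    return X, y


class TestFitStump:
    def test_perfectly_separable_midpoint(self):
        X = np.array([[0.4], [0.5], [1.5], [1.6]])
        y = np.array([1, 1, 0, 0])  # actives below
        clf = fit_stump(X, y)
        assert clf.threshold_ == pytest.approx(1.0)
        assert clf.orientation_ == "active"
        assert clf.train_impurity_ == 0.0
        assert clf.train_balanced_accuracy_ == 1.0

    def test_tie_breaks_to_lower_column(self):
        col = np.array([0.4, 0.5, 1.5, 1.6])
        X = np.column_stack([col, col])  # two identical separable columns
        y = np.array([1, 1, 0, 0])
        assert fit_stump(X, y).column_ == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            X, y = random_instance(rng)
            clf = fit_stump(X, y)
            imp, j, thr, orient = brute_force_stump(X, y)
            assert clf.train_impurity_ == imp
            assert clf.column_ == j
            assert clf.threshold_ == thr
            assert clf.orientation_ == orient

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_stump(np.random.default_rng(0).uniform(size=(5, 2)), np.ones(5, dtype=int))

    def test_accepts_fluctuation_matrix_and_keeps_column_ids(self, small_panel):
        clf = fit_stump(small_panel)
        assert clf.column_ in small_panel.values.columns
        preds = clf.predict(small_panel)
        assert set(preds) <= {"active", "inactive"}

    def test_sklearn_params_round_trip(self):
        clf = DecisionStumpClassifier()
        assert clf.get_params() == {}
        clf.set_params()


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "y_true, y_pred, expected",
        [
            ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),
            ([1, 1, 0, 0], [1, 1, 1, 1], 0.5),  # all-active floor
            ([1, 1, 0, 0], [1, 1, 1, 0], 0.75),  # sens 1.0, spec 0.5
        ],
    )
    def test_formula(self, y_true, y_pred, expected):
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(expected)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import balanced_accuracy_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            yt = rng.integers(0, 2, 30)
            yp = rng.integers(0, 2, 30)
            if yt.min() == yt.max():
                continue
            assert balanced_accuracy(yt, yp) == pytest.approx(
                balanced_accuracy_score(yt, yp)
            )

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            balanced_accuracy([1, 1, 1], [1, 0, 1])


class TestResampledEvaluation:
    def test_noise_free_ceiling(self):
        spec = PanelSpec(
            n_active=10, n_inactive=10, n_columns=6, signal_column=2,
            mu_active=0.4, mu_inactive=1.6, sigma_within=0.05, corr_block=(), seed=0,
        )
        fm, _ = gen_fluctuation_panel(spec)
        rep = resampled_evaluation(fm, repeats=30, base_seed=1)
        assert rep.mean_balanced_accuracy == 1.0
        assert rep.sd_balanced_accuracy == 0.0
        assert rep.column_selection_frequency == {2: 1.0}

    def test_split_sizes_for_43_systems(self, panel):
        rep = resampled_evaluation(panel, train_fraction=0.7, repeats=10, base_seed=0)
        assert all(r["n_train"] == 30 and r["n_validation"] == 13 for r in rep.records)

    def test_seed_determinism(self, small_panel):
        a = resampled_evaluation(small_panel, repeats=15, base_seed=42)
        b = resampled_evaluation(small_panel, repeats=15, base_seed=42)
        assert a.to_dict() == b.to_dict()
        c = resampled_evaluation(small_panel, repeats=15, base_seed=43)
        assert a.records != c.records

    def test_label_shuffle_gives_chance_level(self, small_panel):
        rng = np.random.default_rng(5)
        means = []
        for s in range(25):
            shuffled = FluctuationMatrix(
                values=small_panel.values,
                labels=small_panel.labels.sample(
                    frac=1.0, random_state=s
                ).set_axis(small_panel.labels.index),
            )
            rep = resampled_evaluation(shuffled, repeats=10, base_seed=s)
            means.append(rep.mean_balanced_accuracy)
        assert abs(np.mean(means) - 0.5) < 0.1

    def test_frequencies_sum_to_one(self, small_panel):
        rep = resampled_evaluation(small_panel, repeats=20, base_seed=3)
        assert sum(rep.column_selection_frequency.values()) == pytest.approx(1.0)


class TestAblation:
    def test_single_round_equals_one_evaluation(self, small_panel):
        rep = resampled_evaluation(small_panel, repeats=20, base_seed=0)
        abl = ablation_cascade(small_panel, rounds=1, repeats=20, base_seed=0)
        assert abl.rounds[0]["selected_column"] == rep.modal_column
        assert abl.rounds[0]["mean_balanced_accuracy"] == rep.mean_balanced_accuracy

    def test_cascade_follows_correlation_structure(self):
        # signal then correlated block before any background column
        hits = 0
        for seed in range(10):
            spec = PanelSpec(
                n_active=12, n_inactive=12, n_columns=10, signal_column=2,
                corr_block=(5, 7), rho=0.95, seed=seed,
            )
            fm, _ = gen_fluctuation_panel(spec)
            abl = ablation_cascade(fm, rounds=3, repeats=30, base_seed=seed)
            sel = abl.selected_columns()
            if sel[0] == 2 and set(sel[1:]) == {5, 7}:
                hits += 1
        assert hits >= 8

    def test_accuracy_degrades_after_informative_columns_removed(self):
        spec = PanelSpec(
            n_active=12, n_inactive=12, n_columns=8, signal_column=3,
            corr_block=(), seed=9,
        )
        fm, _ = gen_fluctuation_panel(spec)
        abl = ablation_cascade(fm, rounds=2, repeats=40, base_seed=2)
        r0, r1 = abl.rounds
        # monotone degradation within one sd
        assert r1["mean_balanced_accuracy"] <= (
            r0["mean_balanced_accuracy"] + r0["sd_balanced_accuracy"]
        )
        # only noise remains after the signal column is removed
        assert abs(r1["mean_balanced_accuracy"] - 0.5) < 0.08


class TestLasso:
    def test_signal_column_tops_ranking(self):
        hits = 0
        for seed in range(20):
            spec = PanelSpec(
                n_active=12, n_inactive=12, n_columns=10, signal_column=4,
                corr_block=(), seed=seed,
            )
            fm, _ = gen_fluctuation_panel(spec)
            ranked = lasso_select(fm, penalty=1.0)
            if ranked and ranked[0][0] == 4:
                hits += 1
        assert hits >= 18

    def test_huge_penalty_shrinks_everything(self, small_panel):
        assert lasso_select(small_panel, penalty=1e6) == []

    def test_vanishing_penalty_matches_unpenalized_logistic(self):
        # 2-column orthogonal design with class overlap (finite MLE); oracle
        # is an independent optimizer on the standardized logistic loss.
        rng = np.random.default_rng(7)
        n = 120
        X = np.column_stack([np.repeat([1.0, -1.0], n // 2), np.tile([1.0, -1.0], n // 2)])
        logits = 0.8 * X[:, 0] - 0.4 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)

        Z = (X - X.mean(axis=0)) / X.std(axis=0)

        def nll(params):
            b0, b = params[0], params[1:]
            z = b0 + Z @ b
            return np.sum(np.logaddexp(0, z) - y * z)

        oracle = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12).x[1:]
        ranked = dict(lasso_select(X, y, penalty=1e-9))
        assert ranked[0] == pytest.approx(oracle[0], abs=1e-4)
        assert ranked[1] == pytest.approx(oracle[1], abs=1e-4)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lasso_select(np.ones((6, 3)), np.array([0, 1, 0, 1, 0, 1]))


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 10_000))
def test_stump_oracle_property(seed):
    """fit_stump equals the exhaustive oracle on arbitrary random instances."""
    rng = np.random.default_rng(seed)
    X, y = random_instance(rng, max_rows=12, max_cols=6)
    clf = fit_stump(X, y)
    imp, j, thr, orient = brute_force_stump(X, y)
    assert (clf.train_impurity_, clf.column_, clf.threshold_, clf.orientation_) == (
        imp, j, thr, orient
    )
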