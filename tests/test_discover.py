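"""Fisher discriminant, leave-one-out cross-validation and subset search."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import breathpanel as bp
from breathpanel.lda import FisherLDA, loocv_accuracy_subsets


def _two_gaussians(n, delta, rng, p=2, cov=None):
    cov = np.eye(p) if cov is None else cov
    X = np.vstack(
        [
            rng.multivariate_normal(np.zeros(p), cov, n),
            rng.multivariate_normal(delta, cov, n),
        ]
    )
    y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
    return X, y


class TestFisherLDA:
    def test_one_dimensional_midpoint_threshold(self):
        X = np.array([[0.0], [0.2], [-0.2], [2.0], [1.8], [2.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = bp.fit_lda(X, y)
        assert model.coef_[0] > 0
        assert model.threshold_ / model.coef_[0] == pytest.approx(1.0)

    def test_direction_matches_closed_form_fisher(self):
        rng = np.random.default_rng(0)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        delta = np.array([1.0, 0.5])
        X, y = _two_gaussians(5000, delta, rng, cov=cov)
        model = bp.fit_lda(X, y)
        w_true = np.linalg.solve(cov, delta)
        cosine = w_true @ model.coef_ / (
            np.linalg.norm(w_true) * np.linalg.norm(model.coef_)
        )
        assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) < 2.0

    def test_agrees_with_sklearn_reference(self):
        rng = np.random.default_rng(1)
        X, y = _two_gaussians(100, np.array([1.0, 0.3, -0.5]), rng, p=3)
        ours = bp.fit_lda(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        labels, _ = bp.predict_lda(ours, X)
        assert np.mean(labels == ref.predict(X)) > 0.97

    def test_tie_scores_classified_positive(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        model = bp.fit_lda(X, y)
        boundary = np.array([[model.threshold_ / model.coef_[0]]])
        assert model.predict(boundary)[0] == 1

    def test_training_means_classified_correctly(self):
        rng = np.random.default_rng(2)
        X, y = _two_gaussians(30, np.array([2.0, 0.0]), rng)
        model = bp.fit_lda(X, y)
        assert model.predict(model.means_[1][None, :])[0]
        assert not model.predict(model.means_[0][None, :])[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bp.fit_lda(np.zeros((5, 2)), np.ones(5))

    def test_sklearn_estimator_protocol(self):
        model = FisherLDA(shrinkage=0.2)
        assert clone(model).get_params()["shrinkage"] == 0.2
        model.set_params(shrinkage=0.5)
        assert model.shrinkage == 0.5


class TestLOOCV:
    def test_perfectly_separated_scores_one(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert bp.loocv_accuracy(X, y) == 1.0

    def test_xor_is_not_linearly_solvable(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([0, 0, 1, 1])
        # shrinkage keeps the 3-point folds non-singular; a linear rule
        # still cannot solve the parity arrangement
        assert bp.loocv_accuracy(X, y, shrinkage=0.5) <= 0.5

    def test_identical_means_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = np.arange(60) < 30
        acc = bp.loocv_accuracy(X, y)
        assert 0.23 <= acc <= 0.77  # 99% binomial band around 0.5 at n=60 is ~(0.33,0.67)

    def test_label_shuffle_null_is_centred(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = np.arange(30) < 15
        accs = []
        for _ in range(40):
            accs.append(bp.loocv_accuracy(X, rng.permutation(y)))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_scale_invariance_without_shrinkage(self):
        rng = np.random.default_rng(5)
        X, y = _two_gaussians(15, np.array([1.0, 0.2]), rng)
        base = bp.loocv_accuracy(X, y, shrinkage=0.0)
        X2 = X.copy()
        X2[:, 1] *= 1000.0
        assert bp.loocv_accuracy(X2, y, shrinkage=0.0) == base


class TestSubsetSearch:
    def test_batched_engine_matches_reference_loop(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(18, 7))
        y = np.arange(18) < 10
        subsets = np.array(list(itertools.combinations(range(7), 3)))
        for lam in (0.0, 0.1):
            acc, _ = loocv_accuracy_subsets(X, y, subsets, shrinkage=lam)
            ref = np.array(
                [bp.loocv_accuracy(X[:, list(s)], y, shrinkage=lam) for s in subsets]
            )
            np.testing.assert_array_equal(acc, ref)

    def test_exhaustive_count_is_binomial_coefficient(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 12))
        y = np.arange(12) < 6
        res = bp.subset_search(X, y, k=3)
        assert res.n_evaluated == 220  # C(12, 3)
        assert res.subsets.shape == (220, 3)

    def test_single_informative_feature_found(self):
        rng = np.random.default_rng(8)
        X, y = bp.simulate_feature_matrix(18, 18, 10, (4,), 2.5, rng)
        res = bp.subset_search(X, y, k=1)
        assert res.best_subset == (4,)

    def test_planted_triple_recovered_at_large_effect(self):
        rng = np.random.default_rng(9)
        X, y = bp.simulate_feature_matrix(18, 18, 12, (1, 5, 9), 3.0, rng)
        res = bp.subset_search(X, y, k=3)
        assert set(res.best_subset) == {1, 5, 9}

    def test_greedy_never_beats_exhaustive(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            X, y = bp.simulate_feature_matrix(12, 12, 8, (0, 3), 1.5, r)
            ex = bp.subset_search(X, y, k=3, mode="exhaustive")
            gr = bp.subset_search(X, y, k=3, mode="greedy")
            assert gr.accuracies[gr.order[0]] <= ex.best_accuracy + 1e-12

    def test_over_budget_exhaustive_advises_greedy(self):
        X = np.zeros((10, 50))
        y = np.arange(10) < 5
        with pytest.raises(ValueError, match="greedy"):
            bp.subset_search(X, y, k=4, max_subsets=1000)

    def test_ranking_is_deterministic(self):
        rng = np.random.default_rng(11)
        X, y = bp.simulate_feature_matrix(12, 12, 8, (0,), 1.0, rng)
        r1 = bp.subset_search(X, y, k=2)
        r2 = bp.subset_search(X, y, k=2)
        np.testing.assert_array_equal(r1.order, r2.order)
        # ranking non-increasing in (accuracy, separation)
        acc = r1.accuracies[r1.order]
        assert np.all(np.diff(acc) <= 1e-12)

    def test_selector_transform_keeps_panel_columns(self):
        rng = np.random.default_rng(12)
        X, y = bp.simulate_feature_matrix(15, 15, 6, (2,), 3.0, rng)
        sel = bp.PanelSelector(k=2).fit(X, y)
        assert sel.transform(X).shape == (30, 2)
        assert sel.get_support().sum() == 2
        assert 2 in sel.best_subset_
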