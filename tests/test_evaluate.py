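"""Diagnostic metrics, panel evaluation and principal-component projection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import PCA as SkPCA

import breathpanel as bp
from breathpanel.evaluate import PanelPCA, _round1

counts = st.integers(min_value=0, max_value=500)


class TestConfusionMetrics:
    def test_reported_combined_set_statistics(self):
        # 36 CRC / 32 HC, 34 true positives, 28 true negatives
        cm = bp.confusion_metrics(tp=34, fp=4, tn=28, fn=2)
        assert cm.sensitivity == 94.4
        assert cm.specificity == 87.5
        assert cm.ppv == 89.5
        assert cm.npv == 93.3
        assert cm.accuracy == 91.2

    def test_reported_testing_set_statistics(self):
        cm = bp.confusion_metrics(tp=17, fp=3, tn=11, fn=1)
        assert cm.specificity == 78.6
        assert cm.ppv == 85.0
        assert cm.npv == 91.7
        assert cm.accuracy == 87.5

    def test_perfect_classifier_all_hundred(self):
        cm = bp.confusion_metrics(tp=7, fp=0, tn=9, fn=0)
        assert (
            cm.sensitivity == cm.specificity == cm.ppv == cm.npv == cm.accuracy == 100.0
        )

    def test_undefined_ratios_are_nan_not_zero(self):
        cm = bp.confusion_metrics(tp=0, fp=0, tn=5, fn=0)
        assert math.isnan(cm.sensitivity) and math.isnan(cm.ppv)
        assert cm.specificity == 100.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bp.confusion_metrics(0, 0, 0, 0)
        with pytest.raises(ValueError):
            bp.confusion_metrics(-1, 1, 1, 1)

    def test_rounding_half_away_from_zero(self):
        assert _round1(87.25) == 87.3
        assert _round1(94.44999) == 94.4
        assert _round1(85.0) == 85.0

    @given(tp=counts, fp=counts, tn=counts, fn=counts)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identities_and_additivity(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        cm = bp.confusion_metrics(tp, fp, tn, fn)
        if tp + fn:
            assert cm.sensitivity == _round1(100 * tp / (tp + fn))
        if tn + fp:
            assert cm.specificity == _round1(100 * tn / (tn + fp))
        assert cm.accuracy == _round1(100 * (tp + tn) / cm.total)
        other = bp.confusion_metrics(fn, tn, fp, tp)  # arbitrary second set
        combined = cm + other
        assert (combined.tp, combined.fp, combined.tn, combined.fn) == (
            tp + fn,
            fp + tn,
            tn + fp,
            fn + tp,
        )


class TestPanelPCA:
    def test_single_axis_data_explains_everything(self):
        rng = np.random.default_rng(0)
        X = np.zeros((50, 3))
        X[:, 1] = rng.normal(size=50)
        scores, loadings, evr = bp.pca_project(X)
        assert evr[0] == pytest.approx(1.0)

    def test_known_covariance_eigen_fractions(self):
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal([0, 0], [[2.0, 0.0], [0.0, 1.0]], 10_000)
        _, _, evr = bp.pca_project(X)
        assert evr[0] == pytest.approx(2 / 3, abs=0.02)
        assert evr[1] == pytest.approx(1 / 3, abs=0.02)

    def test_fit_row_scores_centred_and_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        scores, loadings, evr = bp.pca_project(X, fit_rows=np.arange(20))
        np.testing.assert_allclose(scores[:20].mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(loadings @ loadings.T, np.eye(3), atol=1e-9)
        assert evr.sum() == pytest.approx(1.0)

    def test_matches_sklearn_up_to_convention(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        ours = PanelPCA().fit(X)
        ref = SkPCA().fit(X)
        np.testing.assert_allclose(
            ours.explained_variance_ratio_, ref.explained_variance_ratio_, atol=1e-9
        )
        for j in range(4):
            dot = abs(ours.components_[j] @ ref.components_[j])
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            PanelPCA().fit(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            PanelPCA().fit(np.zeros((10, 1)))
        with pytest.raises(ValueError):
            PanelPCA().fit(np.zeros((10, 3)))


def _feature_matrix(X, sample_ids):
    fids = [f"rt{100 + 10 * j:06.1f}" for j in range(X.shape[1])]
    values = pd.DataFrame(X, index=sample_ids, columns=fids)
    features = pd.DataFrame(
        {"feature_id": fids, "consensus_rt": [100.0 + 10 * j for j in range(X.shape[1])]}
    )
    return bp.FeatureMatrix(values=values, features=features)


def _manifest(sample_ids, groups, n_train_per_group=10):
    man = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    return bp.assign_roles(man, n_train_crc=n_train_per_group, n_train_hc=n_train_per_group)


class TestEvaluatePanel:
    def _cohort(self, effect, seed, n_crc=18, n_hc=16, p=5):
        rng = np.random.default_rng(seed)
        X, y = bp.simulate_feature_matrix(n_crc, n_hc, p, (0, 2, 4), effect, rng)
        ids = [f"s{i:03d}" for i in range(len(y))]
        groups = np.where(y, "CRC", "HC")
        return _feature_matrix(X, ids), _manifest(ids, groups, n_train_per_group=9)

    def test_combined_counts_are_cellwise_sums(self):
        fm, man = self._cohort(effect=1.0, seed=0)
        rep = bp.evaluate_panel(fm, man, [0, 2, 4])
        tr, te, co = rep.metrics["training"], rep.metrics["testing"], rep.metrics["combined"]
        for cell in ("tp", "fp", "tn", "fn"):
            assert getattr(co, cell) == getattr(tr, cell) + getattr(te, cell)

    def test_strong_effect_classifies_almost_everything(self):
        hits = 0
        for seed in range(10):
            fm, man = self._cohort(effect=3.0, seed=seed)
            rep = bp.evaluate_panel(fm, man, [0, 2, 4])
            hits += rep.metrics["combined"].accuracy >= 90.0
        assert hits >= 9

    def test_training_only_report_warns_on_empty_test_set(self):
        fm, man = self._cohort(effect=2.0, seed=1)
        man["role"] = "train"
        with pytest.warns(UserWarning, match="empty test set"):
            rep = bp.evaluate_panel(fm, man, [0, 2])
        assert "testing" not in rep.metrics

    def test_pca_scores_cover_all_samples(self):
        fm, man = self._cohort(effect=1.0, seed=2)
        rep = bp.evaluate_panel(fm, man, [0, 2, 4])
        assert len(rep.pca_scores) == len(fm.values)
        assert rep.explained_variance_ratio is not None
        assert sum(rep.explained_variance_ratio) == pytest.approx(1.0)

    def test_unknown_panel_feature_rejected(self):
        fm, man = self._cohort(effect=1.0, seed=3)
        with pytest.raises(ValueError, match="panel"):
            bp.evaluate_panel(fm, man, ["rt999.9"])

    def test_report_serializes_and_tabulates(self):
        fm, man = self._cohort(effect=1.0, seed=4)
        rep = bp.evaluate_panel(fm, man, [0, 2, 4])
        table = rep.table_frame()
        assert list(table.columns) == [
            "Training Set",
            "Testing Set",
            "Training + Testing Set",
        ]
        assert table.loc["Subject number", "Training + Testing Set"] == 34
        assert "metrics" in rep.to_json()
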