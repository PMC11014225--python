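"""Peak picking, integration, alignment, annotation and the feature matrix."""

import numpy as np
import pandas as pd
import pytest

import breathpanel as bp
from breathpanel.chromatogram import Chromatogram, Stage
from breathpanel.peaks import Peak

TWO_PI = 2.0 * np.pi


def _corrected(x, dt=0.1):
    t = np.arange(len(x)) * dt
    return Chromatogram("s", t, np.asarray(x, float), stage=Stage.BASELINE_CORRECTED)


def _gaussian(t, mu, sigma, h):
    return h * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


class TestDetect:
    def test_single_gaussian_closed_form_area(self):
        t = np.arange(0, 60, 0.1)
        h, sigma, mu = 2.0, 1.5, 30.0
        peaks = bp.detect_peaks(_corrected(_gaussian(t, mu, sigma, h)))
        assert len(peaks) == 1
        p = peaks[0]
        assert abs(p.apex_time - mu) <= 0.1 + 1e-9
        assert p.apex_height == pytest.approx(h, rel=1e-6)
        assert p.area == pytest.approx(h * sigma * np.sqrt(TWO_PI), rel=0.01)

    def test_two_resolved_gaussians(self):
        t = np.arange(0, 100, 0.1)
        sigma = 1.5
        x = _gaussian(t, 40, sigma, 1.0) + _gaussian(t, 40 + 6 * sigma, sigma, 1.0)
        assert len(bp.detect_peaks(_corrected(x))) == 2

    def test_flat_zero_trace_has_no_peaks(self):
        assert bp.detect_peaks(_corrected(np.zeros(500))) == []

    def test_requires_baseline_corrected_stage(self):
        chrom = Chromatogram("s", np.arange(100) * 0.1, np.zeros(100), stage=Stage.RAW)
        with pytest.raises(ValueError, match="baseline-corrected"):
            bp.detect_peaks(chrom)


class TestIntegrate:
    def test_rectangle_area(self):
        x = np.zeros(300)
        x[100:201] = 1.0  # 10 s plateau at dt = 0.1
        chrom = _corrected(x)
        assert bp.integrate_peak(chrom, (10.0, 20.0)) == pytest.approx(10.0)

    def test_zero_trace_integrates_to_zero(self):
        assert bp.integrate_peak(_corrected(np.zeros(300)), (5.0, 20.0)) == 0.0

    def test_out_of_grid_bounds_rejected(self):
        with pytest.raises(ValueError):
            bp.integrate_peak(_corrected(np.zeros(300)), (10.0, 99.0))

    def test_negative_area_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            area = bp.integrate_peak(_corrected(-np.ones(300)), (5.0, 10.0))
        assert area == 0.0


def _peaklist(apexes, area=1.0):
    return [
        Peak(apex_time=a, apex_height=1.0, area=area, left=a - 2, right=a + 2, prominence=1.0)
        for a in apexes
    ]


class TestAlign:
    def test_identical_peaklists_give_one_feature_per_peak(self):
        apexes = [20.0, 50.0, 90.0]
        peaklists = {f"s{i}": _peaklist(apexes) for i in range(5)}
        al = bp.align_samples(peaklists)
        assert len(al.features) == 3
        assert np.allclose(al.shifts.to_numpy(), 0.0)
        assert not al.areas.isna().any().any()

    def test_global_shift_corrected_by_anchors(self):
        apexes = np.array([20.0, 50.0, 90.0])
        peaklists = {f"a{i}": _peaklist(apexes) for i in range(4)}
        peaklists.update({f"b{i}": _peaklist(apexes + 2.0) for i in range(4)})
        al = bp.align_samples(peaklists, anchor_rts=apexes)
        assert len(al.features) == 3
        np.testing.assert_allclose(
            [al.shifts[f"b{i}"] for i in range(4)], 2.0, atol=1e-9
        )

    def test_permutation_invariance_in_sample_order(self):
        rng = np.random.default_rng(0)
        peaklists = {
            f"s{i}": _peaklist(np.sort(rng.uniform(10, 110, 6))) for i in range(6)
        }
        al1 = bp.align_samples(peaklists)
        reordered = {k: peaklists[k] for k in reversed(list(peaklists))}
        al2 = bp.align_samples(reordered)
        np.testing.assert_allclose(
            al1.features["consensus_rt"], al2.features["consensus_rt"]
        )
        pd.testing.assert_frame_equal(
            al1.areas.sort_index(), al2.areas.sort_index()
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            bp.align_samples({}, tolerance=-1)
        with pytest.raises(ValueError):
            bp.align_samples({}, min_presence=0.0)


class TestMatchLibrary:
    def test_known_biomarker_rows(self):
        lib = bp.load_default_library()
        ann = bp.match_library(np.array([197.0, 470.0]), lib)
        assert ann["annotation"].tolist() == [
            "2,4-dimethylhexane",
            "Hexane, 2,2,5,5-tetramethyl-",
        ]

    def test_duplicate_names_carry_rt_qualifier(self):
        lib = bp.load_default_library()
        ann = bp.match_library(np.array([341.5]), lib)
        assert ann["annotation"].iloc[0] == "Heptane, 2,5-dimethyl- @341s"

    def test_empty_and_unmatched(self):
        lib = bp.load_default_library()
        assert len(bp.match_library(np.array([]), lib)) == 0
        ann = bp.match_library(np.array([100.0]), lib)  # no record within 3 s
        assert ann["annotation"].iloc[0] is None

    def test_one_to_one_closest_wins(self):
        lib = bp.load_default_library()
        # two features both near the 197 record: only the closer is annotated
        ann = bp.match_library(np.array([196.5, 198.5]), lib)
        assert ann["annotation"].iloc[0] == "2,4-dimethylhexane"
        assert ann["annotation"].iloc[1] is None


class TestFeatureMatrix:
    def _alignment(self, values):
        sample_ids = [f"s{i}" for i in range(values.shape[0])]
        fids = [f"rt{100 + 10 * j:06.1f}" for j in range(values.shape[1])]
        areas = pd.DataFrame(values, index=sample_ids, columns=fids)
        features = pd.DataFrame(
            {
                "feature_id": fids,
                "consensus_rt": [100.0 + 10 * j for j in range(values.shape[1])],
                "n_present": values.shape[0],
            }
        )
        return bp.Alignment(
            features=features,
            areas=areas,
            apex_times=areas.copy(),
            shifts=pd.Series(0.0, index=sample_ids),
        )

    def test_scaling_all_areas_cancels_in_standardization(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(size=(8, 4))
        al1 = self._alignment(values)
        al2 = self._alignment(2.0 * values)
        train = [f"s{i}" for i in range(4)]
        fm1 = bp.build_feature_matrix(al1, train)
        fm2 = bp.build_feature_matrix(al2, train)
        np.testing.assert_allclose(
            fm1.values.to_numpy(), fm2.values.to_numpy(), atol=1e-12
        )

    def test_no_leak_from_test_rows(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(size=(10, 5))
        train = [f"s{i}" for i in range(5)]
        al = self._alignment(values)
        fm = bp.build_feature_matrix(al, train)
        shuffled = values.copy()
        shuffled[5:] = shuffled[[7, 9, 5, 8, 6]]  # permute test rows only
        fm2 = bp.build_feature_matrix(self._alignment(shuffled), train)
        np.testing.assert_allclose(
            fm.values.loc[train].to_numpy(), fm2.values.loc[train].to_numpy()
        )
        assert fm.transform["center"] == fm2.transform["center"]

    def test_constant_features_dropped_with_warning(self):
        values = np.ones((6, 3))
        values[:, 2] = np.arange(6) + 1.0
        al = self._alignment(values)
        with pytest.warns(UserWarning, match="zero-variance"):
            fm = bp.build_feature_matrix(al, [f"s{i}" for i in range(3)])
        assert fm.values.shape[1] == 1

    def test_absent_peaks_imputed_at_floor(self):
        values = np.array([[1.0, np.nan], [2.0, 4.0], [3.0, 5.0], [4.0, 6.0]])
        al = self._alignment(values)
        fm = bp.build_feature_matrix(al, ["s0", "s1", "s2", "s3"])
        assert not fm.values.isna().any().any()
        # the imputed entry is the most negative in its column
        assert fm.values.iloc[0, 1] == fm.values.iloc[:, 1].min()

    def test_planted_effect_recovered_in_matrix(self, default_cohort):
        # mean standardized group difference over the three biomarker
        # columns tracks the generative effect size within 30%
        cfg, _, manifest, truth, _, _, fm = default_cohort
        from conftest import planted_feature_indices

        man = manifest.set_index("sample_id")
        train = manifest.loc[manifest["role"] == "train", "sample_id"].tolist()
        y = (man.loc[train, "group"] == "CRC").to_numpy()
        X = fm.values.loc[train]
        ds = []
        for j in planted_feature_indices(truth, fm):
            col = X.iloc[:, j].to_numpy()
            n1, n0 = y.sum(), (~y).sum()
            pooled = np.sqrt(
                ((n1 - 1) * col[y].var(ddof=1) + (n0 - 1) * col[~y].var(ddof=1))
                / (n1 + n0 - 2)
            )
            ds.append((col[y].mean() - col[~y].mean()) / pooled)
        assert len(ds) == 3
        assert np.mean(ds) == pytest.approx(cfg.effect_size, rel=0.30)


def test_consensus_features_cover_planted_biomarkers(default_cohort):
    _, _, _, truth, _, alignment, fm = default_cohort
    cons = fm.features["consensus_rt"].to_numpy()
    for brt in truth.panel["rt"]:
        assert np.min(np.abs(cons - brt)) <= 3.0
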