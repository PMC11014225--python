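"""Shared fixtures: a tiny fast cohort and the full default cohort.

Everything is generated programmatically; the only on-disk fixture is the
packaged compound library.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import breathpanel as bp

warnings.filterwarnings("ignore", message=".*duplicate compound names.*")


@pytest.fixture(scope="session")
def small_library(tmp_path_factory) -> str:
    """Three-compound library for fast, fully controlled simulations."""
    path = tmp_path_factory.mktemp("lib") / "small_library.tsv"
    path.write_text("rt_s\tname\n30\tcompound A\n60\tcompound B\n90\tcompound C\n")
    return str(path)


@pytest.fixture()
def small_config(small_library) -> bp.SimulationConfig:
    """Fast cohort: 4+4 samples, 120 s run, one planted biomarker at 60 s."""
    return bp.SimulationConfig(
        n_crc=4,
        n_hc=4,
        library_path=small_library,
        biomarker_rts=(60.0,),
        n_unknown=3,
        duration=120.0,
        n_train_crc=2,
        n_train_hc=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default simulated cohort (seed 0) taken through peak extraction.

    Returns (config, chromatograms, manifest, truth, peaklists, alignment,
    feature_matrix); shared across tests because simulation plus
    pre-processing of 68 full-length traces is the expensive part.
    """
    cfg = bp.SimulationConfig(seed=0)
    chroms, manifest, truth = bp.simulate_cohort(cfg)
    processed = [bp.baseline_correct(bp.denoise(c)) for c in chroms]
    peaklists = {c.sample_id: bp.detect_peaks(c) for c in processed}
    anchors = bp.estimate_anchor_rts(
        processed, candidate_rts=cfg.library().rts, n_anchors=12
    )
    alignment = bp.align_samples(peaklists, anchor_rts=anchors)
    train_ids = manifest.loc[manifest["role"] == "train", "sample_id"].tolist()
    annotations = bp.match_library(
        alignment.features["consensus_rt"].to_numpy(), cfg.library()
    )
    fm = bp.build_feature_matrix(alignment, train_ids, annotations=annotations)
    return cfg, chroms, manifest, truth, peaklists, alignment, fm


def pipeline_null_run(seed: int) -> float:
    """End-to-end held-out test accuracy for an effect-free cohort.

    Selection is confined to the training rows; the returned accuracy is the
    testing-set percentage.  Used by the null-calibration checks.
    """
    cfg = bp.SimulationConfig(seed=seed, effect_size=0.0)
    chroms, manifest, _ = bp.simulate_cohort(cfg)
    processed = [bp.baseline_correct(bp.denoise(c)) for c in chroms]
    peaklists = {c.sample_id: bp.detect_peaks(c) for c in processed}
    anchors = bp.estimate_anchor_rts(
        processed, candidate_rts=cfg.library().rts, n_anchors=12
    )
    alignment = bp.align_samples(peaklists, anchor_rts=anchors)
    train_ids = manifest.loc[manifest["role"] == "train", "sample_id"].tolist()
    fm = bp.build_feature_matrix(alignment, train_ids)
    man = manifest.set_index("sample_id")
    X = fm.values.loc[train_ids].to_numpy(dtype=float)
    y = (man.loc[train_ids, "group"] == "CRC").to_numpy()
    result = bp.subset_search(X, y, k=3, shrinkage=0.1)
    report = bp.evaluate_panel(fm, manifest, list(result.best_subset), shrinkage=0.1)
    return report.metrics["testing"].accuracy


def planted_feature_indices(truth, fm) -> set[int]:
    """Column indices of the planted biomarker features in a feature matrix."""
    rts = (
        fm.features.set_index("feature_id")
        .loc[list(fm.values.columns), "consensus_rt"]
        .to_numpy()
    )
    planted = set()
    for brt in truth.panel["rt"]:
        d = np.abs(rts - brt)
        if d.min() <= 3.0:
            planted.add(int(np.argmin(d)))
    return planted
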