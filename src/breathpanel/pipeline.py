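"""End-to-end pipeline: simulate -> preprocess/QC -> features -> discover -> evaluate.

Each stage reads its inputs from and writes its outputs to a run directory,
so the stages compose: running them one at a time over the same directory is
identical to one ``run_pipeline`` call.  Reruns with the same configuration
and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .chromatogram import Chromatogram, Stage, read_chromatogram, write_chromatogram
from .config import RunConfig
from .evaluate import EvaluationReport, evaluate_panel
from .library import CompoundLibrary, load_default_library, load_library
from .peaks import (
    FeatureMatrix,
    align_samples,
    build_feature_matrix,
    detect_peaks,
    estimate_anchor_rts,
    match_library,
)
from .preprocess import baseline_correct, denoise, filter_inadequate, qc_cohort
from .search import PanelSelector
from .simulate import assign_roles, simulate_cohort

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_preprocess",
    "stage_features",
    "stage_discover",
    "stage_evaluate",
]

log = logging.getLogger("breathpanel.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _library(config: RunConfig) -> CompoundLibrary:
    if config.simulate is not None and config.simulate.library_path is not None:
        return load_library(config.simulate.library_path)
    return load_default_library()


def _read_manifest(path: Path) -> pd.DataFrame:
    man = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "group"}
    if not required <= set(man.columns):
        raise StageError("io", f"{path}: manifest needs columns {sorted(required)}")
    return man


# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, out: Path) -> None:
    """Generate the synthetic cohort and write raw traces + manifest + truth."""
    if config.simulate is None:
        log.info("simulate: no section configured, skipping")
        return
    chroms, manifest, truth = simulate_cohort(config.simulate)
    raw_dir = out / "chromatograms"
    for chrom in chroms:
        write_chromatogram(chrom, raw_dir)
    manifest.to_csv(out / "manifest.csv", index=False)
    truth.write(out / "truth")
    log.info("simulate: wrote %d chromatograms", len(chroms))


def _load_raw(config: RunConfig, out: Path) -> tuple[list[Chromatogram], pd.DataFrame]:
    src = Path(config.input_dir) if config.input_dir else out
    manifest = _read_manifest(src / "manifest.csv")
    raw_dir = src / "chromatograms"
    chroms = []
    for sid in manifest["sample_id"]:
        path = raw_dir / f"{sid}.csv"
        if not path.exists():
            raise StageError("preprocess", f"missing chromatogram for sample {sid}")
        chroms.append(read_chromatogram(path))
    return chroms, manifest


def stage_preprocess(config: RunConfig, out: Path) -> None:
    """QC-filter the raw traces, then denoise and baseline-correct."""
    chroms, manifest = _load_raw(config, out)
    pp = config.preprocess
    reports = qc_cohort(
        chroms,
        floor_fraction=pp.floor_fraction,
        ceiling=pp.ceiling,
        anchor_candidates=_library(config).rts,
        n_anchors=pp.n_anchors,
        min_anchors=pp.min_anchors,
        max_saturation=pp.max_saturation,
    )
    with open(out / "qc_reports.jsonl", "w", encoding="utf-8") as fh:
        for rep in reports:
            fh.write(json.dumps(rep.to_dict(), sort_keys=True) + "\n")
    retained = filter_inadequate(chroms, reports)
    n_excluded = len(chroms) - len(retained)
    log.info("preprocess: QC excluded %d of %d samples", n_excluded, len(chroms))

    kept_ids = {c.sample_id for c in retained}
    man = manifest[manifest["sample_id"].isin(kept_ids)].reset_index(drop=True)
    if n_excluded or "role" not in man.columns:
        sim = config.simulate
        man = assign_roles(
            man.drop(columns=["role"], errors="ignore"),
            n_train_crc=sim.n_train_crc if sim else 18,
            n_train_hc=sim.n_train_hc if sim else 18,
        )
    man.to_csv(out / "manifest_retained.csv", index=False)

    proc_dir = out / "processed"
    for chrom in retained:
        corrected = baseline_correct(
            denoise(chrom, window=pp.window, polyorder=pp.polyorder),
            smoothness=pp.smoothness,
            asymmetry=pp.asymmetry,
            max_iter=pp.max_iter,
        )
        write_chromatogram(corrected, proc_dir)
    log.info("preprocess: wrote %d corrected traces", len(retained))


def stage_features(config: RunConfig, out: Path) -> None:
    """Detect, align and annotate peaks; build the feature matrix."""
    manifest = _read_manifest(out / "manifest_retained.csv")
    proc_dir = out / "processed"
    chroms = [
        read_chromatogram(proc_dir / f"{sid}.csv", stage=Stage.BASELINE_CORRECTED)
        for sid in manifest["sample_id"]
    ]
    pk = config.peaks
    peaklists = {
        c.sample_id: detect_peaks(c, min_prominence=pk.min_prominence, min_snr=pk.min_snr)
        for c in chroms
    }
    library = _library(config)
    # more anchors than QC uses: shift estimation benefits from every
    # isolated, consistently present landmark
    anchors = estimate_anchor_rts(chroms, candidate_rts=library.rts, n_anchors=12)
    alignment = align_samples(
        peaklists,
        tolerance=pk.tolerance,
        min_presence=pk.min_presence,
        anchor_rts=anchors,
    )
    annotations = match_library(alignment.features["consensus_rt"].to_numpy(), library)
    train_ids = manifest.loc[manifest["role"] == "train", "sample_id"].tolist()
    fm = build_feature_matrix(alignment, train_ids, annotations=annotations)
    fm.write(out / "features")
    log.info(
        "features: %d consensus features across %d samples", fm.values.shape[1], fm.values.shape[0]
    )


def _load_features(out: Path) -> FeatureMatrix:
    fdir = out / "features"
    values = pd.read_csv(fdir / "feature_matrix.csv", index_col="sample_id")
    features = pd.read_csv(fdir / "features_meta.csv")
    with open(fdir / "transform.json", "r", encoding="utf-8") as fh:
        transform = json.load(fh)
    return FeatureMatrix(values=values, features=features, transform=transform)


def stage_discover(config: RunConfig, out: Path) -> None:
    """Exhaustive (or greedy) panel search on the training rows only."""
    fm = _load_features(out)
    manifest = _read_manifest(out / "manifest_retained.csv").set_index("sample_id")
    roles = manifest.loc[fm.values.index, "role"]
    groups = manifest.loc[fm.values.index, "group"]
    train = roles == "train"
    X = fm.values.loc[train.to_numpy()].to_numpy(dtype=float)
    y = (groups[train.to_numpy()] == "CRC").to_numpy()

    dc = config.discover
    selector = PanelSelector(
        k=dc.k, mode=dc.mode, shrinkage=dc.shrinkage, max_subsets=dc.max_subsets
    ).fit(X, y, feature_names=list(fm.values.columns))
    result = selector.result_
    log.info(
        "discover: evaluated %d subsets; best %s (cv accuracy %.3f)",
        result.n_evaluated,
        result.best_names(),
        result.best_accuracy,
    )
    ddir = out / "discover"
    ddir.mkdir(parents=True, exist_ok=True)
    result.to_frame(top=dc.top_results).to_csv(ddir / "search_results.csv", index=False)
    ann = fm.features.set_index("feature_id")
    best = result.best_names()
    payload = {
        "panel": best,
        "annotations": [
            None if pd.isna(a) else a
            for a in (ann.loc[best, "annotation"] if "annotation" in ann else [None] * len(best))
        ],
        "cv_accuracy": result.best_accuracy,
        "separation": float(result.separations[result.order[0]]),
        "mode": result.mode,
        "n_evaluated": result.n_evaluated,
    }
    with open(ddir / "best_panel.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def stage_evaluate(config: RunConfig, out: Path) -> EvaluationReport:
    """Apply the selected panel to all samples; write the evaluation report."""
    fm = _load_features(out)
    manifest = _read_manifest(out / "manifest_retained.csv")
    with open(out / "discover" / "best_panel.json", "r", encoding="utf-8") as fh:
        panel = json.load(fh)["panel"]
    report = evaluate_panel(
        fm,
        manifest,
        panel,
        shrinkage=config.evaluate.shrinkage,
        refit_pca_all=config.evaluate.refit_pca_all,
    )
    report.write(out / "evaluate")
    acc = report.metrics.get("combined", report.metrics["training"]).accuracy
    log.info("evaluate: combined accuracy %.1f%%", acc)
    return report


_STAGES = (
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("features", stage_features),
    ("discover", stage_discover),
    ("evaluate", stage_evaluate),
)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> EvaluationReport:
    """Execute every stage into ``out_dir``; returns the evaluation report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write_yaml(out / "resolved_config.yaml")
    report = None
    for name, stage in _STAGES:
        try:
            result = stage(config, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise StageError(name, str(exc)) from exc
        if name == "evaluate":
            report = result
    return report
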