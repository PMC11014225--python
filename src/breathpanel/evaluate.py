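"""Diagnostic evaluation of a biomarker panel.

Fits the Fisher discriminant on the training rows of the feature matrix
restricted to the panel, predicts training, testing and combined sets, and
derives the standard diagnostic-test statistics (sensitivity, specificity,
positive/negative predictive value, total accuracy) from the confusion
counts, with percentages rounded half-away-from-zero to one decimal.  Also
produces principal-component projections of the panel for visualisation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .lda import FisherLDA
from .peaks import FeatureMatrix

__all__ = [
    "ConfusionMetrics",
    "EvaluationReport",
    "confusion_metrics",
    "evaluate_panel",
    "PanelPCA",
    "pca_project",
]

CRC, HC = "CRC", "HC"


def _round1(x: float) -> float:
    """Round half away from zero to one decimal (the convention of the
    clinical statistics this mirrors)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _ratio_pct(num: int, den: int) -> float:
    """Percentage, or NaN when the denominator is zero (never silently 0)."""
    if den == 0:
        return math.nan
    return _round1(100.0 * num / den)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived percentages for one evaluation set."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("at least one count must be positive")
        object.__setattr__(self, "sensitivity", _ratio_pct(self.tp, self.tp + self.fn))
        object.__setattr__(self, "specificity", _ratio_pct(self.tn, self.tn + self.fp))
        object.__setattr__(self, "ppv", _ratio_pct(self.tp, self.tp + self.fp))
        object.__setattr__(self, "npv", _ratio_pct(self.tn, self.tn + self.fn))
        object.__setattr__(
            self, "accuracy", _ratio_pct(self.tp + self.tn, self.total)
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMetrics") -> "ConfusionMetrics":
        return ConfusionMetrics(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )

    def to_dict(self) -> dict:
        def _clean(v: float):
            return None if math.isnan(v) else v

        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": _clean(self.sensitivity),
            "specificity": _clean(self.specificity),
            "ppv": _clean(self.ppv),
            "npv": _clean(self.npv),
            "accuracy": _clean(self.accuracy),
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Build :class:`ConfusionMetrics` from raw counts."""
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class PanelPCA(BaseEstimator, TransformerMixin):
    """Principal components by eigendecomposition of the fit-row covariance.

    Components are orthonormal rows of ``components_``, ordered by
    decreasing explained variance; the sign convention makes each
    component's largest-magnitude loading positive.  ``transform`` centers
    on the fit-row means, so new (e.g. test) rows project into the training
    coordinate frame.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 fit rows")
        if X.shape[1] < 2:
            raise ValueError("PCA needs at least 2 dimensions")
        self.mean_ = X.mean(axis=0)
        xc = X - self.mean_
        cov = xc.T @ xc / (X.shape[0] - 1)
        if not np.any(np.diag(cov) > 0):
            raise ValueError("zero-variance panel: PCA undefined")
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        for j in range(evecs.shape[1]):
            if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.components_ = evecs.T
        self.explained_variance_ = evals
        self.explained_variance_ratio_ = evals / evals.sum()
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


def pca_project(
    X, fit_rows: np.ndarray | list[int] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores, loadings and explained-variance fractions of a panel matrix.

    Components are fitted on ``fit_rows`` (default: all rows) and all rows
    are projected.
    """
    X = np.asarray(X, dtype=float)
    fit_X = X if fit_rows is None else X[np.asarray(fit_rows)]
    pca = PanelPCA().fit(fit_X)
    return pca.transform(X), pca.components_, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# panel evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-set confusion metrics, per-sample predictions, and PCA scores."""

    panel: list[str]
    metrics: dict  # keys: training, testing, combined -> ConfusionMetrics
    predictions: pd.DataFrame  # sample_id, group, role, score, predicted
    pca_scores: pd.DataFrame | None = None
    explained_variance_ratio: list[float] | None = None
    pca_loadings: list[list[float]] | None = None

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "metrics": {k: v.to_dict() for k, v in self.metrics.items() if v is not None},
            "predictions": self.predictions.to_dict(orient="records"),
            "pca": None
            if self.pca_scores is None
            else {
                "scores": self.pca_scores.round(6).to_dict(orient="records"),
                "explained_variance_ratio": [
                    round(float(v), 6) for v in self.explained_variance_ratio
                ],
                "loadings": [
                    [round(float(v), 6) for v in row] for row in self.pca_loadings
                ],
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=False)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "evaluation.json").write_text(self.to_json(), encoding="utf-8")
        self.table_frame().to_csv(directory / "metrics_table.csv")
        if self.pca_scores is not None:
            self.pca_scores.to_csv(directory / "pca_scores.csv", index=False)

    def table_frame(self) -> pd.DataFrame:
        """Metrics in the conventional published layout: one column per
        evaluation set, one row per statistic, percentages to one decimal."""
        cols = {}
        names = {
            "training": "Training Set",
            "testing": "Testing Set",
            "combined": "Training + Testing Set",
        }
        for key, colname in names.items():
            cm = self.metrics.get(key)
            if cm is None:
                continue
            cols[colname] = {
                "Subject number": cm.total,
                "Positive": cm.tp + cm.fp,
                "Negative": cm.tn + cm.fn,
                "Specificity": cm.specificity,
                "Sensitivity": cm.sensitivity,
                "Positive predictive value": cm.ppv,
                "Negative predictive value": cm.npv,
                "Total accuracy": cm.accuracy,
            }
        return pd.DataFrame(cols)


def _set_metrics(pred_pos: np.ndarray, is_crc: np.ndarray) -> ConfusionMetrics:
    return ConfusionMetrics(
        tp=int(np.sum(pred_pos & is_crc)),
        fp=int(np.sum(pred_pos & ~is_crc)),
        tn=int(np.sum(~pred_pos & ~is_crc)),
        fn=int(np.sum(~pred_pos & is_crc)),
    )


def evaluate_panel(
    feature_matrix: FeatureMatrix,
    manifest: pd.DataFrame,
    panel: list[str] | tuple[int, ...],
    shrinkage: float = 0.1,
    refit_pca_all: bool = False,
) -> EvaluationReport:
    """Fit the panel discriminant on training rows and report all sets.

    ``panel`` is a list of feature-matrix column names (or integer column
    positions).  The discriminant and the PCA frame are fitted on the
    training rows only unless ``refit_pca_all``.
    """
    values = feature_matrix.values
    if all(isinstance(j, (int, np.integer)) for j in panel):
        panel = [values.columns[int(j)] for j in panel]
    panel = list(panel)
    missing = [c for c in panel if c not in values.columns]
    if missing:
        raise ValueError(f"panel features not in matrix: {missing}")

    man = manifest.set_index("sample_id")
    uncovered = [sid for sid in values.index if sid not in man.index]
    if uncovered:
        raise ValueError(f"manifest does not cover samples: {uncovered}")
    roles = man.loc[values.index, "role"]
    groups = man.loc[values.index, "group"]

    X = values[panel].to_numpy(dtype=float)
    is_train = (roles == "train").to_numpy()
    is_crc = (groups == CRC).to_numpy()

    model = FisherLDA(shrinkage=shrinkage, positive_label=True).fit(
        X[is_train], is_crc[is_train]
    )
    scores = model.score_samples(X)
    pred_pos = model.decision_function(X) >= 0.0

    predictions = pd.DataFrame(
        {
            "sample_id": values.index,
            "group": groups.to_numpy(),
            "role": roles.to_numpy(),
            "score": np.round(scores, 6),
            "predicted": np.where(pred_pos, CRC, HC),
        }
    ).reset_index(drop=True)

    metrics = {"training": _set_metrics(pred_pos[is_train], is_crc[is_train])}
    if np.any(~is_train):
        metrics["testing"] = _set_metrics(pred_pos[~is_train], is_crc[~is_train])
        metrics["combined"] = metrics["training"] + metrics["testing"]
    else:
        warnings.warn("empty test set: training-only report", stacklevel=2)

    pca_scores = None
    evr = None
    loadings = None
    if len(panel) >= 2:
        fit_rows = None if refit_pca_all else np.flatnonzero(is_train)
        scores_mat, comps, evr_arr = pca_project(X, fit_rows)
        pca_scores = pd.DataFrame(
            scores_mat, columns=[f"PC{i + 1}" for i in range(scores_mat.shape[1])]
        )
        pca_scores.insert(0, "sample_id", values.index.to_numpy())
        pca_scores.insert(1, "group", groups.to_numpy())
        pca_scores.insert(2, "role", roles.to_numpy())
        evr = [float(v) for v in evr_arr]
        loadings = comps.tolist()

    return EvaluationReport(
        panel=panel,
        metrics=metrics,
        predictions=predictions,
        pca_scores=pca_scores,
        explained_variance_ratio=evr,
        pca_loadings=loadings,
    )
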