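"""Biomarker-panel search: exhaustive (or greedy) k-subset selection.

Every candidate subset of k features is scored by leave-one-out
cross-validated accuracy of a Fisher discriminant on the training rows; ties
are broken by the larger full-training-set Fisher separation
``J = dmu' S_lambda^-1 dmu`` and finally by the lexicographically smallest
feature-index tuple, so the ranking is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .lda import loocv_accuracy_subsets

__all__ = ["SubsetSearchResult", "PanelSelector", "subset_search"]

DEFAULT_SHRINKAGE = 0.1
MAX_EXHAUSTIVE_SUBSETS = 1_000_000


@dataclass
class SubsetSearchResult:
    """Ranked outcome of a panel search."""

    subsets: np.ndarray  # (m, k) evaluated feature-index tuples
    accuracies: np.ndarray  # (m,) LOOCV accuracies
    separations: np.ndarray  # (m,) tie-break Fisher separations
    order: np.ndarray  # ranking permutation, best first
    mode: str
    n_evaluated: int
    feature_names: list[str] | None = None

    @property
    def best_subset(self) -> tuple[int, ...]:
        return tuple(int(j) for j in self.subsets[self.order[0]])

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies[self.order[0]])

    def best_names(self) -> list[str] | None:
        if self.feature_names is None:
            return None
        return [self.feature_names[j] for j in self.best_subset]

    def to_frame(self, top: int | None = None) -> pd.DataFrame:
        """Ranked table of evaluated subsets (optionally the top rows only)."""
        sel = self.order if top is None else self.order[:top]
        subs = self.subsets[sel]
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(sel) + 1),
                "subset": [",".join(map(str, row)) for row in subs],
                "cv_accuracy": self.accuracies[sel],
                "separation": self.separations[sel],
            }
        )
        if self.feature_names is not None:
            df["features"] = [
                ";".join(self.feature_names[j] for j in row) for row in subs
            ]
        return df


def _rank(subsets: np.ndarray, acc: np.ndarray, sep: np.ndarray) -> np.ndarray:
    """Best-first order: accuracy desc, separation desc, index tuple asc."""
    keys = tuple(subsets[:, j] for j in range(subsets.shape[1] - 1, -1, -1))
    return np.lexsort(keys + (-sep, -acc))


def subset_search(
    X,
    y,
    k: int = 3,
    mode: str = "exhaustive",
    shrinkage: float = DEFAULT_SHRINKAGE,
    feature_names: list[str] | None = None,
    max_subsets: int = MAX_EXHAUSTIVE_SUBSETS,
) -> SubsetSearchResult:
    """Search all (or greedily grown) k-feature subsets of the training data.

    ``y`` may be boolean or two-label; the positive class is the larger
    label in sorted order for non-boolean input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype != bool:
        labels = np.unique(y)
        if labels.size != 2:
            raise ValueError("exactly two classes required")
        y = y == labels[1]
    p = X.shape[1]
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")

    if mode == "exhaustive":
        n_total = comb(p, k)
        if n_total > max_subsets:
            raise ValueError(
                f"exhaustive search over C({p},{k})={n_total} subsets exceeds the "
                f"budget of {max_subsets}; use mode='greedy'"
            )
        subsets = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(p), k)),
            dtype=int,
            count=n_total * k,
        ).reshape(n_total, k)
        acc, sep = loocv_accuracy_subsets(X, y, subsets, shrinkage=shrinkage)
        order = _rank(subsets, acc, sep)
        return SubsetSearchResult(
            subsets=subsets,
            accuracies=acc,
            separations=sep,
            order=order,
            mode="exhaustive",
            n_evaluated=n_total,
            feature_names=feature_names,
        )

    if mode == "greedy":
        selected: list[int] = []
        all_subs, all_acc, all_sep = [], [], []
        for _ in range(k):
            remaining = [j for j in range(p) if j not in selected]
            cand = np.asarray([sorted(selected + [j]) for j in remaining], dtype=int)
            acc, sep = loocv_accuracy_subsets(X, y, cand, shrinkage=shrinkage)
            best = _rank(cand, acc, sep)[0]
            selected = list(cand[best])
            all_subs.append(cand)
            all_acc.append(acc)
            all_sep.append(sep)
        # report only complete k-subsets from the last round, ranked
        subsets, acc, sep = all_subs[-1], all_acc[-1], all_sep[-1]
        order = _rank(subsets, acc, sep)
        n_evaluated = int(sum(len(a) for a in all_acc))
        return SubsetSearchResult(
            subsets=subsets,
            accuracies=acc,
            separations=sep,
            order=order,
            mode="greedy",
            n_evaluated=n_evaluated,
            feature_names=feature_names,
        )

    raise ValueError(f"unknown mode {mode!r}")


class PanelSelector(BaseEstimator):
    """Feature-subset selector scored by LOOCV of a Fisher discriminant.

    scikit-learn-style transformer: ``fit(X, y)`` runs the search on the
    given (training) rows; ``transform(X)`` keeps the selected panel columns.

    Attributes
    ----------
    best_subset_ : tuple of int
    result_ : SubsetSearchResult
    n_evaluated_ : int
    """

    def __init__(
        self,
        k: int = 3,
        mode: str = "exhaustive",
        shrinkage: float = DEFAULT_SHRINKAGE,
        max_subsets: int = MAX_EXHAUSTIVE_SUBSETS,
    ):
        self.k = k
        self.mode = mode
        self.shrinkage = shrinkage
        self.max_subsets = max_subsets

    def fit(self, X, y, feature_names: list[str] | None = None):
        self.result_ = subset_search(
            X,
            y,
            k=self.k,
            mode=self.mode,
            shrinkage=self.shrinkage,
            feature_names=feature_names,
            max_subsets=self.max_subsets,
        )
        self.best_subset_ = self.result_.best_subset
        self.n_evaluated_ = self.result_.n_evaluated
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, list(self.best_subset_)]

    def get_support(self) -> np.ndarray:
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[list(self.best_subset_)] = True
        return mask
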