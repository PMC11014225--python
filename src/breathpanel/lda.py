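"""Two-class Fisher linear discriminant analysis, built from first principles.

The classifier projects features onto ``w = S_lambda^-1 (mu_pos - mu_neg)``,
where ``S_lambda = (1 - lambda) S + lambda (tr S / p) I`` is the pooled
within-class covariance shrunk toward a scaled identity, and thresholds the
projection at the midpoint of the projected class means (equal priors).  A
score exactly at the threshold is classified positive.

Also provides leave-one-out cross-validated accuracy, both as a simple
reference loop and as a batched engine that evaluates many feature subsets
at once via rank-one downdates of the pooled scatter (used by the
exhaustive panel search).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["FisherLDA", "fit_lda", "predict_lda", "loocv_accuracy"]


class FisherLDA(BaseEstimator, ClassifierMixin):
    """Two-class Fisher discriminant with optional covariance shrinkage.

    Parameters
    ----------
    shrinkage : float in [0, 1]
        Weight of the scaled-identity target; 0 reproduces textbook LDA.
    positive_label : hashable, optional
        Which class is "positive" (diseased).  Defaults to the last class in
        sorted order (``True`` for boolean labels).

    Attributes
    ----------
    coef_ : ndarray (p,)
        Discriminant weight vector w.
    threshold_ : float
        Decision threshold on the score ``w . x``; scores >= threshold are
        classified positive.
    classes_ : ndarray (2,)
        ``[negative_label, positive_label]``.
    means_ : ndarray (2, p)
        Class means in the same order as ``classes_``.
    """

    def __init__(self, shrinkage: float = 0.0, positive_label=None):
        self.shrinkage = shrinkage
        self.positive_label = positive_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
        labels = np.unique(y)
        if labels.size != 2:
            raise ValueError(f"exactly two classes required, got {labels.size}")
        if self.positive_label is not None:
            if self.positive_label not in labels:
                raise ValueError(f"positive_label {self.positive_label!r} not in y")
            pos = self.positive_label
            neg = labels[labels != pos][0]
        else:
            neg, pos = labels[0], labels[1]
        mask = y == pos
        n_pos, n_neg = int(mask.sum()), int((~mask).sum())
        n, p = X.shape
        mu_pos = X[mask].mean(axis=0)
        mu_neg = X[~mask].mean(axis=0)
        d_pos = X[mask] - mu_pos
        d_neg = X[~mask] - mu_neg
        scatter = d_pos.T @ d_pos + d_neg.T @ d_neg
        cov = scatter / max(n - 2, 1)
        lam = self.shrinkage
        cov_s = (1.0 - lam) * cov + lam * (np.trace(cov) / p) * np.eye(p)
        delta = mu_pos - mu_neg
        try:
            w = np.linalg.solve(cov_s, delta)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular pooled covariance; increase shrinkage"
            ) from exc
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError(
                "non-finite discriminant weights; increase shrinkage"
            )
        self.classes_ = np.asarray([neg, pos])
        self.means_ = np.vstack([mu_neg, mu_pos])
        self.coef_ = w
        self.threshold_ = float(w @ (mu_pos + mu_neg) / 2.0)
        self.n_features_in_ = p
        self.counts_ = (n_neg, n_pos)
        return self

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}"
            )
        return X

    def score_samples(self, X) -> np.ndarray:
        """Raw discriminant scores ``w . x``."""
        return self._check_X(X) @ self.coef_

    def decision_function(self, X) -> np.ndarray:
        return self.score_samples(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        positive = self.decision_function(X) >= 0.0  # tie -> positive
        return np.where(positive, self.classes_[1], self.classes_[0])

    def separation_(self) -> float:
        """Training-set Fisher separation J = (w . dmu)^2 / (w' S_lambda w),
        which equals dmu' S_lambda^-1 dmu for the fitted w."""
        delta = self.means_[1] - self.means_[0]
        return float(delta @ self.coef_)


def fit_lda(X, y, shrinkage: float = 0.0, positive_label=None) -> FisherLDA:
    """Functional wrapper over :class:`FisherLDA`."""
    return FisherLDA(shrinkage=shrinkage, positive_label=positive_label).fit(X, y)


def predict_lda(model: FisherLDA, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and raw scores for ``X`` under a fitted model."""
    return model.predict(X), model.score_samples(X)


def loocv_accuracy(X, y, shrinkage: float = 0.0, positive_label=None) -> float:
    """Leave-one-out cross-validated accuracy of :class:`FisherLDA`.

    Deterministic: n fits, each holding out one sample.  If a fold would
    lose a class entirely (a class with a single member), the held-out
    sample is predicted as the remaining class's label, with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 samples")
    correct = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        y_tr = y[keep]
        if np.unique(y_tr).size < 2:
            warnings.warn(
                "a leave-one-out fold lost a class; predicting remaining-class majority",
                stacklevel=2,
            )
            pred = y_tr[0]
        else:
            model = FisherLDA(shrinkage=shrinkage, positive_label=positive_label).fit(
                X[keep], y_tr
            )
            pred = model.predict(X[i])[0]
        correct += pred == y[i]
    return correct / n


# ---------------------------------------------------------------------------
# batched subset engine
# ---------------------------------------------------------------------------


def loocv_accuracy_subsets(
    X: np.ndarray,
    y: np.ndarray,
    subsets: np.ndarray,
    shrinkage: float = 0.0,
    chunk: int = 8192,
) -> tuple[np.ndarray, np.ndarray]:
    """LOOCV accuracy and full-data Fisher separation for many subsets.

    Vectorized over subsets and folds: removing one sample shifts its class
    mean by a closed form and downdates the pooled scatter by a rank-one
    term, so no refitting loop is needed.  Bitwise-equivalent in its
    classification decisions to the reference :func:`loocv_accuracy` loop.

    Parameters
    ----------
    X : (n, p) matrix; ``y`` boolean with True = positive class.
    subsets : (m, k) integer column indices.

    Returns
    -------
    acc : (m,) LOOCV accuracies.
    sep : (m,) separations ``dmu' S_lambda^-1 dmu`` on the full data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    subsets = np.asarray(subsets, dtype=int)
    n = X.shape[0]
    m, k = subsets.shape
    n1 = int(y.sum())
    n0 = n - n1
    if min(n0, n1) < 2:
        raise ValueError("both classes need at least 2 members")
    lam = shrinkage
    eye = np.eye(k)
    fac = np.where(y, n1 / (n1 - 1.0), n0 / (n0 - 1.0))  # scatter downdate factor

    acc = np.empty(m)
    sep = np.empty(m)
    for start in range(0, m, chunk):
        sub = subsets[start : start + chunk]
        b = sub.shape[0]
        Xs = X[:, sub].transpose(1, 0, 2)  # (b, n, k)
        X1, X0 = Xs[:, y], Xs[:, ~y]
        m1 = X1.mean(axis=1)  # (b, k)
        m0 = X0.mean(axis=1)
        d1 = X1 - m1[:, None]
        d0 = X0 - m0[:, None]
        scatter = np.einsum("bni,bnj->bij", d1, d1) + np.einsum("bni,bnj->bij", d0, d0)

        # full-data separation (tie-break score)
        cov_f = scatter / (n - 2)
        tr_f = np.einsum("bii->b", cov_f) / k
        cov_fs = (1 - lam) * cov_f + lam * tr_f[:, None, None] * eye
        dmu_f = m1 - m0
        w_f = np.linalg.solve(cov_fs, dmu_f[..., None])[..., 0]
        sep[start : start + b] = np.einsum("bk,bk->b", dmu_f, w_f)

        # leave-one-out quantities, all folds at once
        mean_own = np.where(y[None, :, None], m1[:, None], m0[:, None])  # (b, n, k)
        d = Xs - mean_own
        outer = np.einsum("bni,bnj->bnij", d, d)
        scatter_loo = scatter[:, None] - fac[None, :, None, None] * outer
        cov = scatter_loo / (n - 3)
        tr = np.einsum("bnii->bn", cov) / k
        cov_s = (1 - lam) * cov + lam * tr[..., None, None] * eye

        s1 = m1 * n1
        s0 = m0 * n0
        m1_loo = np.where(
            y[None, :, None], (s1[:, None] - Xs) / (n1 - 1.0), m1[:, None]
        )
        m0_loo = np.where(
            y[None, :, None], m0[:, None], (s0[:, None] - Xs) / (n0 - 1.0)
        )
        dmu = m1_loo - m0_loo
        w = np.linalg.solve(cov_s, dmu[..., None])[..., 0]  # (b, n, k)
        thr = 0.5 * np.einsum("bnk,bnk->bn", w, m1_loo + m0_loo)
        score = np.einsum("bnk,bnk->bn", w, Xs)
        pred_pos = score >= thr
        acc[start : start + b] = (pred_pos == y[None, :]).mean(axis=1)
    return acc, sep
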