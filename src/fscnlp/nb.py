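"""Multinomial Naive Bayes over selected TF-IDF features.

The classifier applies Bayes' theorem under the feature-independence
assumption.  Class-conditional feature probabilities are estimated from the
accumulated (fractional, TF-IDF-weighted) feature mass of each class with
additive smoothing:

    P(f|c) = (sum_i w_if + alpha) / (sum_i sum_g w_ig + alpha * V)

where the sums run over training documents of class c and V is the
vocabulary size.  ``alpha > 0`` prevents zero probabilities.  Priors are the
training class frequencies.  Prediction scores are

    score_c = log prior_c + sum_f w_f * log P(f|c)

with the posterior obtained by softmax; ties resolve to ``no_epilepsy``
(the clinically conservative call: a false positive medicates
unnecessarily).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

CLASSES = ("epilepsy", "no_epilepsy")


@dataclass
class NBModel:
    classes: tuple[str, str]
    log_priors: np.ndarray  # shape (2,)
    feature_loglik: np.ndarray  # shape (2, V)
    alpha: float
    vocabulary: tuple[str, ...]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "classes": list(self.classes),
            "log_priors": self.log_priors.tolist(),
            "feature_loglik": self.feature_loglik.tolist(),
            "alpha": self.alpha,
            "vocabulary": list(self.vocabulary),
        }
        path.write_text(json.dumps(payload), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "NBModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            classes=tuple(payload["classes"]),
            log_priors=np.array(payload["log_priors"]),
            feature_loglik=np.array(payload["feature_loglik"]),
            alpha=float(payload["alpha"]),
            vocabulary=tuple(payload["vocabulary"]),
        )


def _as_matrix(X) -> sp.csr_matrix:
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.asarray(X, dtype=float))


def fit_nb(
    X,
    labels: Sequence[str],
    alpha: float = 1.0,
    vocabulary: Sequence[str] | None = None,
) -> NBModel:
    """Fit the smoothed multinomial model on (fractional) feature weights.

    ``X`` is documents x features (dense or sparse); ``labels`` are the
    per-document classes, both of which must be present.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    X = _as_matrix(X)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("labels must align with matrix rows")
    present = set(labels.tolist())
    if present != set(CLASSES):
        raise ValueError(f"both classes {CLASSES} must be present, got {sorted(present)}")
    if vocabulary is None:
        vocabulary = tuple(f"f{j}" for j in range(X.shape[1]))
    vocabulary = tuple(vocabulary)
    if len(vocabulary) != X.shape[1]:
        raise ValueError("vocabulary length must match feature count")
    V = X.shape[1]
    log_priors = np.empty(2)
    feature_loglik = np.empty((2, V))
    n = X.shape[0]
    for ci, cls in enumerate(CLASSES):
        mask = labels == cls
        log_priors[ci] = np.log(mask.sum() / n)
        class_mass = np.asarray(X[mask].sum(axis=0)).ravel()
        feature_loglik[ci] = np.log(class_mass + alpha) - np.log(class_mass.sum() + alpha * V)
    return NBModel(
        classes=CLASSES,
        log_priors=log_priors,
        feature_loglik=feature_loglik,
        alpha=float(alpha),
        vocabulary=vocabulary,
    )


def predict_nb(model: NBModel, X, vocabulary: Sequence[str] | None = None):
    """Predict labels and posteriors for documents on the model vocabulary.

    Returns ``(labels, posteriors)`` where ``posteriors[:, 0]`` is
    P(epilepsy | doc).  An all-zero row carries no evidence and returns the
    priors exactly.
    """
    X = _as_matrix(X)
    if X.shape[1] != len(model.vocabulary):
        raise ValueError(
            f"vocabulary mismatch: matrix has {X.shape[1]} features, "
            f"model expects {len(model.vocabulary)}"
        )
    if vocabulary is not None and tuple(vocabulary) != tuple(model.vocabulary):
        raise ValueError("vocabulary mismatch: feature names differ from model vocabulary")
    scores = X @ model.feature_loglik.T + model.log_priors  # (n, 2)
    scores = np.asarray(scores)
    shifted = scores - scores.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    posteriors = expd / expd.sum(axis=1, keepdims=True)
    # Strict inequality: a tie resolves to no_epilepsy.
    labels = np.where(scores[:, 0] > scores[:, 1], CLASSES[0], CLASSES[1])
    return labels, posteriors


def cv_tune_alpha(
    X,
    labels: Sequence[str],
    grid: Sequence[float] = (0.1, 0.5, 1.0, 2.0),
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Pick the smoothing parameter by stratified K-fold CV accuracy.

    Returns the winning alpha (ties -> smaller alpha) and the per-alpha
    mean CV accuracy table.
    """
    from sklearn.model_selection import StratifiedKFold

    X = _as_matrix(X)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    table: dict[float, float] = {}
    for alpha in grid:
        accs = []
        for train_idx, val_idx in skf.split(np.zeros(len(labels)), labels):
            model = fit_nb(X[train_idx], labels[train_idx], alpha=alpha)
            pred, _ = predict_nb(model, X[val_idx])
            accs.append(float(np.mean(pred == labels[val_idx])))
        table[float(alpha)] = float(np.mean(accs))
    best = max(sorted(table), key=lambda a: table[a])
    return best, table
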