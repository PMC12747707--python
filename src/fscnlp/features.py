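"""Document-feature matrices, TF-IDF weighting and feature selection.

All fitting here (document frequencies, pre-ranking, recursive feature
elimination) happens on training documents only; test documents are later
*projected* onto the frozen training features and idf values, so no
information can leak from the test set into the model.

TF-IDF uses the raw-count x log10(N/df) convention.  Pre-ranking keeps the
``prerank_k`` (default 8000) features with the largest total TF-IDF mass;
recursive feature elimination (RFE) then iteratively discards the least
important fraction per round until ``final_k`` (default 300) remain.
Feature importance inside RFE is the 5-fold cross-validated mean of the
magnitude of the smoothed Naive Bayes class log-likelihood contrast
|log P(f|epilepsy) - log P(f|no_epilepsy)|, weighted by the feature's
overall occurrence frequency so that rare features cannot dominate through
sampling noise.  Ties everywhere break lexicographically on the feature name, which
makes selection deterministic across runs and platforms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .nb import NBModel, fit_nb
from .preprocess import NGramDoc


@dataclass
class DocFeatureMatrix:
    """Sparse documents x n-gram features count matrix."""

    doc_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        n, v = self.counts.shape
        if n != len(self.doc_ids) or v != len(self.feature_names):
            raise ValueError("matrix dimensions inconsistent with id/name lists")


@dataclass
class WeightedMatrix:
    """TF-IDF weighted matrix plus the idf table needed to project new docs."""

    doc_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    weights: sp.csr_matrix
    idf: np.ndarray  # per-feature log10(N/df), aligned with feature_names

    @property
    def idf_table(self) -> dict[str, float]:
        return {f: float(v) for f, v in zip(self.feature_names, self.idf)}

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=0)).ravel()

    def column_counts(self) -> np.ndarray:
        """Total raw occurrence count per feature, recovered as weight/idf.

        Features with idf exactly 0 (present in every training document)
        carry zero TF-IDF mass and report count 0 here; they are inert
        under this weighting scheme."""
        sums = self.column_sums()
        counts = np.zeros_like(sums)
        nz = self.idf > 0
        counts[nz] = sums[nz] / self.idf[nz]
        return counts

    def subset(self, names: Sequence[str]) -> "WeightedMatrix":
        index = {f: j for j, f in enumerate(self.feature_names)}
        cols = [index[f] for f in names]
        return WeightedMatrix(
            doc_ids=self.doc_ids,
            feature_names=tuple(names),
            weights=self.weights[:, cols].tocsr(),
            idf=self.idf[cols],
        )


@dataclass(frozen=True)
class FeatureSelectionConfig:
    prerank_k: int = 8000
    final_k: int = 300
    cv_folds: int = 5
    elimination_fraction: float = 0.1
    seed: int = 0
    nb_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.final_k > self.prerank_k:
            raise ValueError("final_k must be <= prerank_k")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.elimination_fraction < 1.0:
            raise ValueError("elimination_fraction must be in (0, 1)")


@dataclass
class SelectedFeatures:
    """Final feature set, ordered by decreasing importance."""

    names: tuple[str, ...]
    importances: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["feature", "importance"])
            for name, imp in zip(self.names, self.importances):
                writer.writerow([name, repr(float(imp))])
        return path


def build_dfm(docs: Sequence[NGramDoc]) -> DocFeatureMatrix:
    """Count matrix over the union of observed features, lexicographic order."""
    if not docs:
        raise ValueError("cannot build a matrix from zero documents")
    vocab = sorted({f for doc in docs for f in doc.features})
    if not vocab:
        raise ValueError("all documents are empty after preprocessing")
    index = {f: j for j, f in enumerate(vocab)}
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for doc in docs:
        row_counts: dict[int, int] = {}
        for f in doc.features:
            j = index[f]
            row_counts[j] = row_counts.get(j, 0) + 1
        for j in sorted(row_counts):
            indices.append(j)
            data.append(row_counts[j])
        indptr.append(len(indices))
    counts = sp.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices), np.array(indptr)),
        shape=(len(docs), len(vocab)),
    )
    return DocFeatureMatrix(
        doc_ids=tuple(doc.id for doc in docs),
        feature_names=tuple(vocab),
        counts=counts,
    )


def tfidf(dfm: DocFeatureMatrix) -> WeightedMatrix:
    """weight[i,j] = count[i,j] * log10(N / df_j).

    A feature present in every document gets idf 0 and therefore all-zero
    weights; the sparsity pattern is otherwise that of the counts.
    """
    n_docs = dfm.counts.shape[0]
    df = np.asarray((dfm.counts > 0).sum(axis=0)).ravel()
    idf = np.log10(n_docs / df)
    weights = dfm.counts.multiply(idf).tocsr()
    weights.eliminate_zeros()
    return WeightedMatrix(
        doc_ids=dfm.doc_ids,
        feature_names=dfm.feature_names,
        weights=weights,
        idf=idf,
    )


def _ordered_top(names: Sequence[str], scores: np.ndarray, k: int) -> list[str]:
    """Top-k names by score, ties broken lexicographically."""
    order = sorted(range(len(names)), key=lambda j: (-scores[j], names[j]))
    return [names[j] for j in order[:k]]


def prerank(weighted: WeightedMatrix, k: int) -> list[str]:
    """The k features with the largest total TF-IDF mass."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return _ordered_top(weighted.feature_names, weighted.column_sums(), k)


def _stratified_fold_train_indices(
    doc_ids: Sequence[str], labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Per-fold training row indices, stratified by label.

    Fold membership is a function of (doc_id, label, seed) only — ids are
    sorted within each class before the seeded shuffle — so cross-validated
    importances are invariant to document order.
    """
    pos = {d: i for i, d in enumerate(doc_ids)}
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(doc_ids), dtype=int)
    for cls in sorted(set(labels.tolist())):
        ids = sorted(d for d, l in zip(doc_ids, labels) if l == cls)
        perm = rng.permutation(len(ids))
        for slot, idx in enumerate(perm):
            fold_of[pos[ids[idx]]] = slot % k
    return [np.flatnonzero(fold_of != f) for f in range(k)]


def _cv_importance(
    W: sp.csr_matrix,
    labels: np.ndarray,
    folds: list[np.ndarray],
    alpha: float,
    freq_weight: np.ndarray,
) -> np.ndarray:
    """CV-mean |log P(f|E) - log P(f|N)| from the smoothed NB fit,
    frequency-weighted."""
    contrasts = np.zeros(W.shape[1])
    for train_idx in folds:
        model = fit_nb(W[train_idx], labels[train_idx], alpha=alpha)
        contrasts += np.abs(model.feature_loglik[0] - model.feature_loglik[1])
    return (contrasts / len(folds)) * freq_weight


def rfe_select(
    weighted: WeightedMatrix,
    labels: Sequence[str],
    config: FeatureSelectionConfig = FeatureSelectionConfig(),
) -> SelectedFeatures:
    """Recursive feature elimination with K-fold cross-validated importance.

    Starts from the pre-ranked top ``prerank_k`` features, removes the
    bottom ``elimination_fraction`` per round, and truncates the final
    round to exactly ``final_k`` by importance.  Deterministic given the
    seed (CV folds are seeded) and invariant to document order.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("rfe_select requires both classes in the labels")
    current = prerank(weighted, min(config.prerank_k, len(weighted.feature_names)))
    W_full = weighted.subset(current)
    # Frequency weight = raw occurrence count: keeps rare features (whose
    # smoothed log-likelihood contrast is dominated by sampling noise) from
    # outranking genuinely frequent discriminative ones.
    freq_full = W_full.column_counts()
    fold_train_idx = _stratified_fold_train_indices(
        weighted.doc_ids, labels, config.cv_folds, config.seed
    )
    names = list(W_full.feature_names)
    W = W_full.weights
    freq = freq_full
    importance = _cv_importance(W, labels, fold_train_idx, config.nb_alpha, freq)
    while len(names) > config.final_k:
        n_drop = max(1, int(len(names) * config.elimination_fraction))
        n_keep = max(config.final_k, len(names) - n_drop)
        kept = _ordered_top(names, importance, n_keep)
        pos = {f: j for j, f in enumerate(names)}
        keep_idx = [pos[f] for f in kept]
        W = W[:, keep_idx].tocsr()
        freq = freq[keep_idx]
        names = kept
        importance = _cv_importance(W, labels, fold_train_idx, config.nb_alpha, freq)
    order = sorted(range(len(names)), key=lambda j: (-importance[j], names[j]))
    return SelectedFeatures(
        names=tuple(names[j] for j in order),
        importances=importance[[j for j in order]],
    )


def project(
    test_docs: Sequence[NGramDoc],
    selected: SelectedFeatures | Sequence[str],
    idf_table: Mapping[str, float],
) -> WeightedMatrix:
    """Represent documents on the selected *training* features with
    training idf values; features unseen in training are ignored."""
    names = tuple(selected.names if isinstance(selected, SelectedFeatures) else selected)
    if not names:
        raise ValueError("cannot project onto an empty feature set")
    index = {f: j for j, f in enumerate(names)}
    idf = np.array([idf_table[f] for f in names])
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for doc in test_docs:
        row_counts: dict[int, int] = {}
        for f in doc.features:
            j = index.get(f)
            if j is not None:
                row_counts[j] = row_counts.get(j, 0) + 1
        for j in sorted(row_counts):
            indices.append(j)
            data.append(row_counts[j] * idf[j])
        indptr.append(len(indices))
    weights = sp.csr_matrix(
        (np.array(data), np.array(indices, dtype=np.int64), np.array(indptr)),
        shape=(len(test_docs), len(names)),
    )
    return WeightedMatrix(
        doc_ids=tuple(d.id for d in test_docs),
        feature_names=names,
        weights=weights,
        idf=idf,
    )


def top_features_per_class(
    model: NBModel, m: int = 25
) -> dict[str, list[tuple[str, float]]]:
    """Per class, the m features with the largest class-favoring
    log-likelihood ratio (the bar-chart style keyword report)."""
    if m < 0:
        raise ValueError("m must be >= 0")
    diff = model.feature_loglik[0] - model.feature_loglik[1]  # >0 favors epilepsy
    names = model.vocabulary
    order_e = sorted(range(len(names)), key=lambda j: (-diff[j], names[j]))
    order_n = sorted(range(len(names)), key=lambda j: (diff[j], names[j]))
    return {
        "epilepsy": [(names[j], float(diff[j])) for j in order_e[:m]],
        "no_epilepsy": [(names[j], float(-diff[j])) for j in order_n[:m]],
    }


def write_top_features_report(
    top: Mapping[str, list[tuple[str, float]]],
    csv_path: str | Path,
    plot_path: str | Path | None = None,
) -> None:
    """Write the per-class top-feature report as CSV and, optionally, a
    horizontal bar chart."""
    csv_path = Path(csv_path)
    with csv_path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "rank", "feature", "log_likelihood_ratio"])
        for cls, pairs in top.items():
            for rank, (name, score) in enumerate(pairs, start=1):
                writer.writerow([cls, rank, name, repr(score)])
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(top), figsize=(6 * len(top), 0.3 * max(len(p) for p in top.values()) + 2))
        if len(top) == 1:
            axes = [axes]
        for ax, (cls, pairs) in zip(axes, top.items()):
            names = [p[0] for p in pairs][::-1]
            scores = [p[1] for p in pairs][::-1]
            ax.barh(names, scores)
            ax.set_title(f"Top features: {cls}")
            ax.set_xlabel("class log-likelihood ratio")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
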