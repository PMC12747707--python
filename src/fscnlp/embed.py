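"""Sentence-embedding representation and boosted linear classification.

Each letter is mapped to a fixed-length dense vector (768 dimensions by
default, matching multilingual Sentence-BERT encoders) and classified with
a *linear booster*: gradient boosting whose base learners are additive
regularized linear updates rather than trees, so the fitted model is a
single logistic-linear scorer.

Two embedding providers are available:

* :class:`MockEmbeddingProvider` (default): a fully offline, seeded
  feature-hashing embedding.  Each normalized token is hashed to a fixed
  pseudo-random Gaussian direction and the document vector is the sum over
  its token multiset, scaled by 1/sqrt(dim).  Deterministic, requires no
  network, preserves token-multiset geometry (shared vocabulary raises
  cosine similarity) and retains length information.
* :class:`SentenceTransformerProvider`: an optional online backend wrapping
  a pretrained multilingual sentence encoder; never required by tests.

Provider-side text normalization (documented, exact): lowercase; fold
accented characters to their ASCII base letter (NFKD, combining marks
dropped); replace every non-alphanumeric character with a space; collapse
whitespace runs.
"""

from __future__ import annotations

import hashlib
import json
import re
import unicodedata
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")


def normalize_for_embedding(text: str) -> list[str]:
    """Lowercase, fold diacritics to ASCII, strip punctuation, split on
    whitespace."""
    text = text.lower()
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = _NON_ALNUM_RE.sub(" ", text)
    return text.split()


@dataclass
class EmbeddingMatrix:
    doc_ids: tuple[str, ...]
    vectors: np.ndarray  # (n_docs, dim)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.doc_ids):
            raise ValueError("row count must match doc_ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding matrix contains non-finite entries")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, vectors=self.vectors, doc_ids=np.array(self.doc_ids))
        return path


class MockEmbeddingProvider:
    """Offline deterministic embedding: seeded token hashing + Gaussian
    directions.

    Same text always maps to the same vector; output dimension is constant
    regardless of input length.
    """

    def __init__(self, dim: int = 768, seed: int = 0):
        self.name = "mock-hash"
        self.dim = int(dim)
        self.seed = int(seed)
        self.deterministic = True
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                token.encode("utf-8"), digest_size=8, person=str(self.seed).encode()[:16]
            ).digest()
            token_seed = int.from_bytes(digest, "big") % (2**31)
            vec = np.random.default_rng(token_seed).standard_normal(self.dim) / np.sqrt(self.dim)
            self._cache[token] = vec
        return vec

    def embed(self, texts: Sequence[str], doc_ids: Sequence[str] | None = None) -> EmbeddingMatrix:
        if doc_ids is None:
            doc_ids = tuple(str(i) for i in range(len(texts)))
        vectors = np.zeros((len(texts), self.dim))
        for i, text in enumerate(texts):
            tokens = normalize_for_embedding(text)
            if not tokens:
                warnings.warn(f"document {doc_ids[i]!r} is empty; embedding as a zero vector")
                continue
            for tok in tokens:
                vectors[i] += self._token_vector(tok)
        return EmbeddingMatrix(doc_ids=tuple(doc_ids), vectors=vectors)


class SentenceTransformerProvider:
    """Optional online backend wrapping a pretrained multilingual sentence
    encoder (downloads model weights on first use)."""

    def __init__(self, model_name: str = "paraphrase-multilingual-mpnet-base-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "sentence-transformers is not installed; use MockEmbeddingProvider "
                "for offline, deterministic embeddings"
            ) from exc
        self.name = model_name
        self._model = SentenceTransformer(model_name)
        self.dim = self._model.get_sentence_embedding_dimension()
        self.deterministic = True

    def embed(self, texts: Sequence[str], doc_ids: Sequence[str] | None = None) -> EmbeddingMatrix:  # pragma: no cover
        if doc_ids is None:
            doc_ids = tuple(str(i) for i in range(len(texts)))
        normalized = [" ".join(normalize_for_embedding(t)) for t in texts]
        vectors = np.asarray(self._model.encode(normalized))
        return EmbeddingMatrix(doc_ids=tuple(doc_ids), vectors=vectors)


def embed(texts: Sequence[str], provider, doc_ids: Sequence[str] | None = None) -> EmbeddingMatrix:
    """Embed texts with the given provider (one dim-length vector each)."""
    return provider.embed(texts, doc_ids=doc_ids)


@dataclass(frozen=True)
class BoostHyperparams:
    """Pinned 'default' hyperparameters of the linear booster."""

    n_rounds: int = 100
    learning_rate: float = 0.5
    l2_penalty: float = 1.0


@dataclass
class BoostedLinearClassifier:
    weights: np.ndarray
    bias: float
    hyperparams: BoostHyperparams
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ValueError("trained weights must be finite")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "hyperparams": {
                "n_rounds": self.hyperparams.n_rounds,
                "learning_rate": self.hyperparams.learning_rate,
                "l2_penalty": self.hyperparams.l2_penalty,
            },
            "threshold": self.threshold,
        }
        path.write_text(json.dumps(payload), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BoostedLinearClassifier":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            weights=np.array(payload["weights"]),
            bias=float(payload["bias"]),
            hyperparams=BoostHyperparams(**payload["hyperparams"]),
            threshold=float(payload["threshold"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_boosted_linear(
    X: EmbeddingMatrix | np.ndarray,
    labels: Sequence[str],
    hyperparams: BoostHyperparams = BoostHyperparams(),
) -> BoostedLinearClassifier:
    """Additive boosting of linear base learners on the logistic loss.

    Each round performs cyclic coordinate Newton updates (bias first, then
    every feature), scaled by the learning rate and shrunk by the L2
    penalty; as rounds grow the model converges toward the L2-regularized
    logistic-regression optimum.  The fit depends on data only through
    sums over documents, so it is invariant to training row order up to
    floating-point summation order.
    """
    M = X.vectors if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite features")
    y = (np.asarray(labels) == "epilepsy").astype(float)
    if len(set(np.asarray(labels).tolist())) < 2:
        raise ValueError("both classes must be present")
    n, d = M.shape
    lam = hyperparams.l2_penalty
    lr = hyperparams.learning_rate
    w = np.zeros(d)
    b = 0.0
    margin = np.zeros(n)
    M = np.asfortranarray(M)  # column access dominates the inner loop
    sq = np.asfortranarray(M * M)
    for _ in range(hyperparams.n_rounds):
        p = _sigmoid(margin)
        g = float(np.sum(p - y))
        h = float(np.sum(p * (1.0 - p))) + 1e-12
        step = lr * g / h
        b -= step
        margin -= step
        for j in range(d):
            p = _sigmoid(margin)
            r = p - y
            g = float(M[:, j] @ r) + lam * w[j]
            h = float(sq[:, j] @ (p * (1.0 - p))) + lam
            step = lr * g / h
            w[j] -= step
            margin -= step * M[:, j]
    return BoostedLinearClassifier(weights=w, bias=b, hyperparams=hyperparams)


def predict_boosted(
    model: BoostedLinearClassifier, X: EmbeddingMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities logistic(w.x + b); label epilepsy iff p > threshold."""
    M = X.vectors if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
    if M.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: inputs have {M.shape[1]} features, "
            f"model expects {model.weights.shape[0]}"
        )
    probs = _sigmoid(M @ model.weights + model.bias)
    labels = np.where(probs > model.threshold, "epilepsy", "no_epilepsy")
    return labels, probs
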