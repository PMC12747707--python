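"""End-to-end model arms with strict train-only fitting.

Each *arm* packages everything fitted on the training letters:

* NB arm: preprocessing config, training idf table, the RFE-selected
  feature set, the CV-chosen smoothing parameter and the fitted Naive
  Bayes model;
* embedding arm: the (seeded, offline) embedding provider and the fitted
  boosted linear classifier.

Test letters only ever pass through ``predict_*``: projection uses the
frozen training idf values and feature set, so replacing or permuting the
test set cannot change any fitted object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .corpus_io import Corpus
from .embed import (
    BoostedLinearClassifier,
    BoostHyperparams,
    MockEmbeddingProvider,
    fit_boosted_linear,
    predict_boosted,
)
from .features import (
    FeatureSelectionConfig,
    SelectedFeatures,
    build_dfm,
    project,
    rfe_select,
    tfidf,
    top_features_per_class,
)
from .nb import NBModel, cv_tune_alpha, fit_nb, predict_nb
from .preprocess import PreprocessConfig, default_dutch_config, preprocess_corpus


@dataclass
class NBArmConfig:
    preprocess: PreprocessConfig = field(default_factory=default_dutch_config)
    selection: FeatureSelectionConfig = field(default_factory=FeatureSelectionConfig)
    alpha_grid: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0)
    cv_folds: int = 5
    #: What the NB event model consumes on the selected features:
    #: "count" (standard multinomial event model, raw occurrence counts) or
    #: "tfidf" (fractional TF-IDF masses).  TF-IDF always drives
    #: pre-ranking and RFE; feeding idf-scaled masses into the likelihood a
    #: second time distorts the evidence of rare features, so counts are
    #: the default.
    event_weighting: str = "count"

    def __post_init__(self) -> None:
        if self.event_weighting not in ("count", "tfidf"):
            raise ValueError("event_weighting must be 'count' or 'tfidf'")


@dataclass
class EmbedArmConfig:
    dim: int = 768
    provider_seed: int = 0
    hyperparams: BoostHyperparams = field(default_factory=BoostHyperparams)


@dataclass
class NBArm:
    config: NBArmConfig
    idf_table: dict[str, float]
    selected: SelectedFeatures
    alpha: float
    alpha_cv_table: dict[float, float]
    model: NBModel


@dataclass
class EmbedArm:
    config: EmbedArmConfig
    provider: MockEmbeddingProvider
    model: BoostedLinearClassifier


def fit_nb_arm(train: Corpus, config: NBArmConfig, seed: int = 0) -> NBArm:
    """Preprocess, weight, select and fit on training letters only."""
    docs = preprocess_corpus(train, config.preprocess)
    weighted = tfidf(build_dfm(docs))
    selection = FeatureSelectionConfig(
        prerank_k=config.selection.prerank_k,
        final_k=config.selection.final_k,
        cv_folds=config.selection.cv_folds,
        elimination_fraction=config.selection.elimination_fraction,
        seed=seed,
        nb_alpha=config.selection.nb_alpha,
    )
    selected = rfe_select(weighted, [l.final_dx for l in train], selection)
    labels = [l.final_dx for l in train]
    if config.event_weighting == "count":
        event_matrix = project(docs, selected, {f: 1.0 for f in selected.names}).weights
    else:
        event_matrix = weighted.subset(list(selected.names)).weights
    alpha, table = cv_tune_alpha(
        event_matrix, labels, grid=config.alpha_grid, folds=config.cv_folds, seed=seed
    )
    model = fit_nb(event_matrix, labels, alpha=alpha, vocabulary=selected.names)
    return NBArm(
        config=config,
        idf_table=weighted.idf_table,
        selected=selected,
        alpha=alpha,
        alpha_cv_table=table,
        model=model,
    )


def predict_nb_arm(arm: NBArm, letters: Corpus) -> tuple[np.ndarray, np.ndarray]:
    docs = preprocess_corpus(letters, arm.config.preprocess)
    if arm.config.event_weighting == "count":
        table = {f: 1.0 for f in arm.selected.names}
    else:
        table = arm.idf_table
    W = project(docs, arm.selected, table)
    return predict_nb(arm.model, W.weights, vocabulary=W.feature_names)


def fit_embed_arm(train: Corpus, config: EmbedArmConfig) -> EmbedArm:
    provider = MockEmbeddingProvider(dim=config.dim, seed=config.provider_seed)
    X = provider.embed([l.anamnesis_text for l in train], doc_ids=train.ids)
    model = fit_boosted_linear(X, [l.final_dx for l in train], config.hyperparams)
    return EmbedArm(config=config, provider=provider, model=model)


def predict_embed_arm(arm: EmbedArm, letters: Corpus) -> tuple[np.ndarray, np.ndarray]:
    X = arm.provider.embed([l.anamnesis_text for l in letters], doc_ids=letters.ids)
    return predict_boosted(arm.model, X)


def nb_arm_top_features(arm: NBArm, m: int = 25):
    return top_features_per_class(arm.model, m)
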