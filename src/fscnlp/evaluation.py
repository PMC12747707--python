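"""Study orchestration and diagnostic-accuracy evaluation.

Two analyses mirror the study design:

* **Analysis A** — letters with a definitive final diagnosis are split
  80/20, stratified by final diagnosis x site; both model arms are trained
  on the training split and evaluated on the held-out split.
* **Analysis B** — the test set is every letter that was 'unclear' at the
  first visit but received a definitive final diagnosis; the models are
  trained on all remaining eligible letters (B test letters are removed
  from the training pool, a deliberately leakage-safe reading).

Letters with a *final* 'unclear' diagnosis are never part of the binary
task; overly short letters are excluded (before splitting) and logged.

Metrics: accuracy, sensitivity, specificity, PPV and NPV with 95%
confidence intervals (Clopper-Pearson exact by default; Wilson and Wald
available).  Positive class = epilepsy.  Paired models on the same test
set are compared with McNemar's test on discordant correctness counts,
with and without continuity correction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.proportion import proportion_confint

from .corpus_io import BINARY_DIAGNOSES, Corpus, exclude_short_letters
from .pipeline import (
    EmbedArmConfig,
    NBArmConfig,
    fit_embed_arm,
    fit_nb_arm,
    nb_arm_top_features,
    predict_embed_arm,
    predict_nb_arm,
)

POSITIVE_CLASS = "epilepsy"

_CI_METHODS = {"beta": "clopper-pearson", "wilson": "wilson", "normal": "wald"}


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    strata: tuple[str, ...]
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]} ...")


def stratified_split(
    corpus: Corpus,
    test_fraction: float = 0.2,
    strata: tuple[str, ...] = ("final_dx", "site"),
    seed: int = 0,
) -> SplitSpec:
    """Seeded stratified split of the binary-eligible letters.

    Within each stratum (by default final diagnosis x site) a random
    ``test_fraction`` sample goes to test, the remainder to train, keeping
    the class and site mix of both halves representative.  A stratum with
    fewer than two letters is assigned to train with a warning.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    eligible = [l for l in corpus if l.final_dx in BINARY_DIAGNOSES]
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[str]] = {}
    for letter in eligible:
        key = tuple(getattr(letter, s) for s in strata)
        groups.setdefault(key, []).append(letter.id)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for key in sorted(groups):
        ids = sorted(groups[key])
        if len(ids) < 2:
            warnings.warn(f"stratum {key} has <2 letters; assigned to train")
            train_ids.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_test = int(round(test_fraction * len(ids)))
        test_pick = {ids[i] for i in perm[:n_test]}
        test_ids.extend(i for i in ids if i in test_pick)
        train_ids.extend(i for i in ids if i not in test_pick)
    order = {lid: k for k, lid in enumerate(corpus.ids)}
    return SplitSpec(
        train_ids=tuple(sorted(train_ids, key=order.get)),
        test_ids=tuple(sorted(test_ids, key=order.get)),
        strata=strata,
        test_fraction=test_fraction,
        seed=seed,
    )


def analysis_b_testset(corpus: Corpus) -> tuple[str, ...]:
    """Ids of letters 'unclear' at the first visit with a definitive final
    diagnosis."""
    ids = tuple(
        l.id
        for l in corpus
        if l.initial_dx == "unclear" and l.final_dx in BINARY_DIAGNOSES
    )
    if not ids:
        warnings.warn("no initially-unclear letters with a definitive final diagnosis")
    return ids


@dataclass
class ConfusionMatrix:
    """2x2 contingency counts; positive class = epilepsy.

    ``n_total`` defaults to the sum of the four cells but can be overridden
    to reproduce published denominators.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_total: int | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        cell_sum = self.tp + self.fp + self.fn + self.tn
        if self.n_total is None:
            self.n_total = cell_sum
        elif self.n_total < cell_sum:
            raise ValueError("n_total cannot be smaller than the cell sum")


def confusion(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionMatrix:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    pos_pred = predicted == POSITIVE_CLASS
    pos_true = truth == POSITIVE_CLASS
    return ConfusionMatrix(
        tp=int(np.sum(pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
    )


@dataclass
class MetricCI:
    value: float
    ci_low: float
    ci_high: float
    method: str
    defined: bool = True
    numerator: int = 0
    denominator: int = 0


@dataclass
class MetricsReport:
    accuracy: MetricCI
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI

    def as_dict(self) -> dict:
        return {k: asdict(v) for k, v in self.__dict__.items()}


def _proportion_ci(x: int, n: int, method: str) -> MetricCI:
    if n == 0:
        return MetricCI(math.nan, math.nan, math.nan, _CI_METHODS[method], defined=False)
    low, high = proportion_confint(x, n, alpha=0.05, method=method)
    return MetricCI(
        value=x / n,
        ci_low=float(low),
        ci_high=float(high),
        method=_CI_METHODS[method],
        numerator=x,
        denominator=n,
    )


def compute_metrics(cm: ConfusionMatrix, ci_method: str = "beta") -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV with 95% CIs.

    Each proportion gets an exact binomial (Clopper-Pearson) interval on
    its own denominator by default.  A zero denominator yields a flagged
    not-a-value metric, never a silent 0.
    """
    if ci_method not in _CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    if cm.n_total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=_proportion_ci(cm.tp + cm.tn, cm.n_total, ci_method),
        sensitivity=_proportion_ci(cm.tp, cm.tp + cm.fn, ci_method),
        specificity=_proportion_ci(cm.tn, cm.tn + cm.fp, ci_method),
        ppv=_proportion_ci(cm.tp, cm.tp + cm.fp, ci_method),
        npv=_proportion_ci(cm.tn, cm.tn + cm.fn, ci_method),
    )


@dataclass
class McNemarResult:
    b: int  # model-1-only-correct discordant pairs
    c: int  # model-2-only-correct discordant pairs
    chi2: float
    df: int
    p: float
    correction: bool


def mcnemar(
    correct1: Sequence[bool], correct2: Sequence[bool], correction: bool = True
) -> McNemarResult:
    """McNemar's chi-square test on paired per-document correctness.

    chi2 = (|b - c| - 1)^2 / (b + c) with continuity correction,
    (b - c)^2 / (b + c) without; p from chi-square with df = 1.  With no
    discordant pairs the statistic is 0 and p = 1.
    """
    correct1 = np.asarray(correct1, dtype=bool)
    correct2 = np.asarray(correct2, dtype=bool)
    if correct1.shape != correct2.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum(correct1 & ~correct2))
    c = int(np.sum(~correct1 & correct2))
    if b + c == 0:
        return McNemarResult(b=b, c=c, chi2=0.0, df=1, p=1.0, correction=correction)
    if correction:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    p = float(chi2_dist.sf(stat, df=1)) if stat > 0 else 1.0
    return McNemarResult(b=b, c=c, chi2=float(stat), df=1, p=p, correction=correction)


# --------------------------------------------------------------------------
# Analysis orchestration
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    nb: NBArmConfig = field(default_factory=NBArmConfig)
    embed: EmbedArmConfig = field(default_factory=EmbedArmConfig)
    arms: tuple[str, ...] = ("nb", "embed")
    test_fraction: float = 0.2
    min_words: int = 20
    ci_method: str = "beta"
    top_m: int = 25


@dataclass
class AnalysisReport:
    analysis: str
    n_train: int
    n_test: int
    excluded_short: list[tuple[str, int]]
    models: dict  # per-arm: metrics, confusion, stratum accuracies
    mcnemar: dict | None
    top_features: dict | None
    nb_alpha: float | None
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self._payload(), indent=2, sort_keys=True), encoding="utf-8")
        return path

    def _payload(self) -> dict:
        return {
            "analysis": self.analysis,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "excluded_short": [list(e) for e in self.excluded_short],
            "models": self.models,
            "mcnemar": self.mcnemar,
            "top_features": self.top_features,
            "nb_alpha": self.nb_alpha,
            "seed": self.seed,
        }


def _cm_dict(cm: ConfusionMatrix) -> dict:
    return {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn, "n_total": cm.n_total}


def _evaluate_arm(
    predicted: np.ndarray,
    test: Corpus,
    ci_method: str,
) -> tuple[dict, np.ndarray]:
    truth = np.array([l.final_dx for l in test])
    cm = confusion(predicted, truth)
    metrics = compute_metrics(cm, ci_method=ci_method)
    correct = predicted == truth
    clear_mask = np.array([l.initial_dx != "unclear" for l in test])
    unclear_mask = ~clear_mask
    entry = {
        "confusion": _cm_dict(cm),
        "metrics": metrics.as_dict(),
        "accuracy_clear_stratum": (
            float(correct[clear_mask].mean()) if clear_mask.any() else None
        ),
        "accuracy_initially_unclear_stratum": (
            float(correct[unclear_mask].mean()) if unclear_mask.any() else None
        ),
        "n_clear": int(clear_mask.sum()),
        "n_initially_unclear": int(unclear_mask.sum()),
    }
    return entry, correct


def _run_arms(
    train: Corpus,
    test: Corpus,
    config: AnalysisConfig,
    seed: int,
    analysis: str,
    excluded_short: list[tuple[str, int]],
) -> AnalysisReport:
    models: dict = {}
    correctness: dict[str, np.ndarray] = {}
    top = None
    nb_alpha = None
    if "nb" in config.arms:
        arm = fit_nb_arm(train, config.nb, seed=seed)
        predicted, _ = predict_nb_arm(arm, test)
        entry, correct = _evaluate_arm(predicted, test, config.ci_method)
        entry["selected_features"] = len(arm.selected)
        entry["alpha"] = arm.alpha
        entry["alpha_cv_table"] = arm.alpha_cv_table
        models["nb"] = entry
        correctness["nb"] = correct
        top = {
            cls: [[name, score] for name, score in pairs]
            for cls, pairs in nb_arm_top_features(arm, config.top_m).items()
        }
        nb_alpha = arm.alpha
    if "embed" in config.arms:
        embed_cfg = EmbedArmConfig(
            dim=config.embed.dim,
            provider_seed=seed if config.embed.provider_seed == 0 else config.embed.provider_seed,
            hyperparams=config.embed.hyperparams,
        )
        arm = fit_embed_arm(train, embed_cfg)
        predicted, _ = predict_embed_arm(arm, test)
        entry, correct = _evaluate_arm(predicted, test, config.ci_method)
        models["embed"] = entry
        correctness["embed"] = correct
    mcnemar_entry = None
    if len(correctness) == 2:
        res_corr = mcnemar(correctness["nb"], correctness["embed"], correction=True)
        res_raw = mcnemar(correctness["nb"], correctness["embed"], correction=False)
        mcnemar_entry = {
            "b": res_corr.b,
            "c": res_corr.c,
            "corrected": {"chi2": res_corr.chi2, "p": res_corr.p},
            "uncorrected": {"chi2": res_raw.chi2, "p": res_raw.p},
            "df": 1,
        }
    return AnalysisReport(
        analysis=analysis,
        n_train=len(train),
        n_test=len(test),
        excluded_short=excluded_short,
        models=models,
        mcnemar=mcnemar_entry,
        top_features=top,
        nb_alpha=nb_alpha,
        seed=seed,
    )


def _eligible(corpus: Corpus, min_words: int):
    filtered, log = exclude_short_letters(corpus, min_words=min_words)
    binary = filtered.subset(
        l.id for l in filtered if l.final_dx in BINARY_DIAGNOSES
    )
    return binary, log


def run_analysis_a(
    corpus: Corpus, config: AnalysisConfig = AnalysisConfig(), seed: int = 0
) -> AnalysisReport:
    """Stratified 80/20 split over both sites; train and test both arms."""
    binary, log = _eligible(corpus, config.min_words)
    split = stratified_split(binary, test_fraction=config.test_fraction, seed=seed)
    train = binary.subset(split.train_ids)
    test = binary.subset(split.test_ids)
    return _run_arms(train, test, config, seed, "A", log)


def run_analysis_b(
    corpus: Corpus, config: AnalysisConfig = AnalysisConfig(), seed: int = 0
) -> AnalysisReport:
    """Test on initially-unclear letters with a definitive final diagnosis;
    train on all other eligible letters (leakage-safe)."""
    binary, log = _eligible(corpus, config.min_words)
    test_ids = analysis_b_testset(binary)
    test_set = set(test_ids)
    train = binary.subset(l.id for l in binary if l.id not in test_set)
    test = binary.subset(test_ids)
    assert not set(train.ids) & set(test.ids)
    return _run_arms(train, test, config, seed, "B", log)
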