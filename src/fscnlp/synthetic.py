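"""Seeded synthetic letter corpora with the statistical structure the
classification pipeline assumes.

Real first-seizure-clinic letters cannot be shared, so every downstream
stage is exercised on generated corpora that emulate the study cohort's
bulk statistics:

* two referring sites with unequal sizes (default 1250:311),
* final-diagnosis mix 32.9% epilepsy / 61.4% no epilepsy / 5.7% unclear,
* an initially-'unclear' stratum (~25.6% of letters at the first visit),
* letter lengths 63-1070 words with median 400 and mean 414 (two-parameter
  log-normal pinned by the median/mean pair, truncated to the range),
* class-conditional keyword signal: per-class lexicons of unigrams and short
  phrases whose occurrence rate is multiplied in letters of their own class,
* frequent Dutch stopword scaffolding, so bigram generation and the
  selective stopword-retention rule are genuinely exercised.

Letters are bags of vocabulary *items* (an item is a word or a short
phrase) drawn i.i.d. from a class-conditional categorical distribution,
dressed up with light sentence scaffolding (capitalization, periods).  The
generative parameters and the realized item counts of every letter are
recorded as :class:`GroundTruth`, which is sufficient to compute the exact
generative log-likelihood of any letter under either class — and hence a
Monte-Carlo estimate of the Bayes-optimal accuracy that upper-bounds any
classifier trained on these corpora.

Letters that are 'unclear' at the first visit have their signal effect
sizes shrunk (``multiplier ** ambiguity_shrink``): clinically ambiguous
cases read more ambiguously.  Letters with a final 'unclear' diagnosis are
drawn from a 50/50 mixture of the two class signal models; they are
excluded from binary training and testing and only their bulk statistics
matter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus_io import Corpus, Letter

__all__ = [
    "LengthModel",
    "VocabSpec",
    "SynthConfig",
    "GroundTruth",
    "LetterTruth",
    "OracleEstimate",
    "default_vocab_spec",
    "paper_calibrated_config",
    "generate_corpus",
    "oracle_bayes_accuracy",
    "length_statistics",
    "write_ground_truth",
    "read_ground_truth",
]


class SynthConfigError(ValueError):
    """The synthetic-corpus configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class LengthModel:
    """Log-normal letter-length model (in words), truncated to a range.

    The two free parameters are pinned by the target median and mean:
    ``mu = ln(median)`` and ``sigma^2 = 2 ln(mean/median)``.
    """

    min_words: int = 63
    max_words: int = 1070
    median_target: float = 400.0
    mean_target: float = 414.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_words <= self.median_target <= self.max_words):
            raise SynthConfigError(
                f"infeasible length model: need min_words <= median <= max_words, "
                f"got {self.min_words} / {self.median_target} / {self.max_words}"
            )
        if self.mean_target < self.median_target:
            raise SynthConfigError(
                "log-normal length model requires mean_target >= median_target"
            )

    @property
    def mu(self) -> float:
        return math.log(self.median_target)

    @property
    def sigma(self) -> float:
        return math.sqrt(2.0 * math.log(self.mean_target / self.median_target))

    def sample(self, rng: np.random.Generator) -> int:
        for _ in range(1000):
            length = int(round(math.exp(rng.normal(self.mu, self.sigma))))
            if self.min_words <= length <= self.max_words:
                return length
        return int(np.clip(length, self.min_words, self.max_words))


@dataclass(frozen=True)
class VocabSpec:
    """Background lexicon, stopword scaffolding and per-class signal items.

    Signal items map item -> occurrence-rate multiplier (the effect size):
    the item's base rate is multiplied by that factor in letters of its own
    class and left at baseline in the other class.  Items may be multi-word
    phrases (space-separated); phrases are emitted as adjacent words, so
    their information survives only as bigram features downstream.
    """

    background: tuple[str, ...]
    stopwords: tuple[str, ...]
    epilepsy_signal: Mapping[str, float]
    control_signal: Mapping[str, float]
    background_weight: float = 1.0
    stopword_weight: float = 8.0
    signal_weight: float = 1.0
    site_b_background_skew: float = 0.0

    def __post_init__(self) -> None:
        stop = set(self.stopwords)
        for name, lex in (("epilepsy", self.epilepsy_signal), ("control", self.control_signal)):
            clash = {item for item in lex if item in stop}
            if clash:
                raise SynthConfigError(
                    f"{name} signal lexicon overlaps the stopword lexicon: {sorted(clash)}"
                )
            bad = {item: m for item, m in lex.items() if m <= 0}
            if bad:
                raise SynthConfigError(f"non-positive signal multipliers: {bad}")
        all_items = self.items
        if len(all_items) != len(set(all_items)):
            raise SynthConfigError("vocabulary items must be unique across lexicons")

    @property
    def items(self) -> tuple[str, ...]:
        return (
            tuple(self.background)
            + tuple(self.stopwords)
            + tuple(self.epilepsy_signal)
            + tuple(self.control_signal)
        )

    def base_weights(self, site: str) -> np.ndarray:
        w = np.concatenate(
            [
                np.full(len(self.background), self.background_weight),
                np.full(len(self.stopwords), self.stopword_weight),
                np.full(len(self.epilepsy_signal), self.signal_weight),
                np.full(len(self.control_signal), self.signal_weight),
            ]
        )
        if site == "site_B" and self.site_b_background_skew:
            nb = len(self.background)
            half = nb // 2
            w[:half] *= 1.0 + self.site_b_background_skew
            w[half:nb] /= 1.0 + self.site_b_background_skew
        return w


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of one synthetic cohort."""

    n_letters: int = 1561
    site_props: tuple[float, float] = (1250 / 1561, 311 / 1561)
    final_dx_props: tuple[float, float, float] = (0.329, 0.614, 0.057)
    #: probability that a letter with a *definitive* final diagnosis was
    #: 'unclear' at the first visit; letters with final 'unclear' are always
    #: initially unclear.  The default reproduces a ~25.6% marginal
    #: initial-'unclear' stratum given 5.7% final-'unclear'.
    p_initial_unclear: float = (0.256 - 0.057) / (1.0 - 0.057)
    length_model: LengthModel = field(default_factory=LengthModel)
    vocab_spec: VocabSpec | None = None
    ambiguity_shrink: float = 0.6
    p_male: float = 0.546
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_letters < 1:
            raise SynthConfigError("n_letters must be positive")
        for name, probs in (("site_props", self.site_props), ("final_dx_props", self.final_dx_props)):
            if any(p < 0 for p in probs) or abs(math.fsum(probs) - 1.0) > 1e-12:
                raise SynthConfigError(f"{name} must be a probability vector summing to 1")
        if not 0.0 <= self.p_initial_unclear <= 1.0:
            raise SynthConfigError("p_initial_unclear must be a probability")
        if not 0.0 < self.ambiguity_shrink <= 1.0:
            raise SynthConfigError("ambiguity_shrink must be in (0, 1]")
        if self.vocab_spec is None:
            object.__setattr__(self, "vocab_spec", default_vocab_spec())


# --------------------------------------------------------------------------
# Default vocabulary.  Background: ordinary Dutch narrative/clinical filler.
# Signal lexicons: ~28 items per class in the spirit of the most
# discriminative reported features (drooling, jerks, her_mouth, slurred
# speech on the epilepsy side; syncope/dizziness semiology on the control
# side), including negation phrases ("geen koorts") and pronoun phrases
# ("haar mond") so the bigram-retention machinery sees real work.
# --------------------------------------------------------------------------

_BACKGROUND_NL = (
    "jongen meisje kind moeder vader ouders broer zus oma opa school thuis klas juf "
    "ochtend middag avond nacht gisteren vandaag weekend vakantie zomer winter "
    "dag week maand jaar moment periode situatie aanleiding reden verhaal "
    "huisarts kinderarts verpleegkundige ziekenhuis polikliniek afspraak verwijzing "
    "voorgeschiedenis zwangerschap bevalling geboorte ontwikkeling groei gewicht lengte "
    "motoriek taalontwikkeling zindelijk peuter kleuter baby "
    "slaap slapen inslapen doorslapen wakker bed bedtijd dromen moe vermoeid uitgerust "
    "eten drinken ontbijt lunch avondeten trek dorst "
    "spelen speeltuin sport voetbal zwemmen gymles fietsen buiten binnen "
    "televisie computer tablet telefoon spelletje boek lezen huiswerk "
    "vriendje vriendinnetje verjaardag feestje logeren "
    "gedrag karakter vrolijk druk rustig verlegen boos blij verdrietig bang "
    "concentratie aandacht geheugen leren rekenen "
    "gezond ziek ziekte klachten symptomen episode voorval gebeurtenis incident "
    "begin duur verloop frequentie patroon herstel "
    "arts onderzoek controle beoordeling indruk observatie beschrijving "
    "medicatie paracetamol vitamines allergie astma eczeem "
    "familie erfelijk neef nicht tante oom "
    "hoofd buik rug nek keel neus oor huid "
    "temperatuur eetlust energie conditie "
    "lagere middelbare groep leerkracht rapport "
    "hond kat huisdier tuin straat buren "
    "auto fiets bus trein onderweg "
    "zaterdag zondag maandag dinsdag woensdag donderdag vrijdag "
    "januari februari maart april juni juli september oktober november december "
    "eerste tweede derde laatste enkele sommige meerdere regelmatig soms vaak zelden "
    "ongeveer ruim bijzonderheden verder overig normaal gebruikelijk"
).split()

_STOPWORDS_NL_GEN = (
    "de het een en van in is dat die op aan met als voor er maar om dan zij hij ze "
    "niet geen ook nog naar bij uit tot door over haar zijn wordt werd heeft hebben "
    "was waren kan zou moet"
).split()

_EPILEPSY_SIGNAL_NL = (
    "trekkingen",
    "schokken",
    "kwijlde",
    "kwijlen",
    "staren",
    "wegdraaien",
    "verstijfde",
    "verkrampt",
    "tongbeet",
    "schuim",
    "blauwverkleuring",
    "incontinentie",
    "ritmisch",
    "schokkend",
    "nastaren",
    "slaperig",
    "verward",
    "smakken",
    "knipperen",
    "grimasseren",
    "aanvalletjes",
    "trillen",
    "haar mond",
    "zijn ogen",
    "niet aanspreekbaar",
    "doorgemaakte aanval",
    "onduidelijke spraak",
    "afgelopen dagen",
)

_CONTROL_SIGNAL_NL = (
    "flauwvallen",
    "flauwgevallen",
    "duizelig",
    "duizeligheid",
    "wegraking",
    "zweterig",
    "misselijk",
    "bleekheid",
    "huilbui",
    "schrikreactie",
    "driftbui",
    "ademinhouding",
    "syncope",
    "collaps",
    "hyperventilatie",
    "hoofdpijn",
    "buikpijn",
    "griepje",
    "verkouden",
    "nachtmerrie",
    "hartkloppingen",
    "sterretjes",
    "opvliegend",
    "benauwd",
    "geen koorts",
    "geen trekkingen",
    "lang staan",
    "warme douche",
)


def default_vocab_spec(
    signal_multiplier: float = 1.4, site_b_background_skew: float = 0.0
) -> VocabSpec:
    """Default vocabulary with a uniform signal effect size.

    ``signal_multiplier=1.4`` gives moderate class separability (a
    Bayes-optimal accuracy around 0.85-0.9 at realistic letter lengths),
    emulating a diagnosable-but-noisy task rather than a trivially
    separable one.
    """
    return VocabSpec(
        background=tuple(_BACKGROUND_NL),
        stopwords=tuple(_STOPWORDS_NL_GEN),
        epilepsy_signal={item: signal_multiplier for item in _EPILEPSY_SIGNAL_NL},
        control_signal={item: signal_multiplier for item in _CONTROL_SIGNAL_NL},
        site_b_background_skew=site_b_background_skew,
    )


def paper_calibrated_config(n_letters: int = 1561, seed: int = 0, **overrides) -> SynthConfig:
    """The cohort-calibrated default configuration (sites 1250:311,
    final-diagnosis mix 32.9/61.4/5.7, lengths 63-1070 / median 400 /
    mean 414)."""
    cfg = SynthConfig(n_letters=n_letters, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LetterTruth:
    """Generative record of one letter: its content class, whether the
    ambiguity shrink was applied, and the realized item counts."""

    id: str
    content_class: str
    shrink_applied: bool
    site: str
    item_counts: dict[str, int]


@dataclass
class GroundTruth:
    """Generative parameters plus per-letter realizations.

    Sufficient to recompute the exact item-level log-likelihood of any
    letter under either binary class (the item-count distribution given the
    number of items is multinomial; letter length is class-independent, so
    it cancels from the likelihood ratio).
    """

    config: SynthConfig
    letters: list[LetterTruth]

    @property
    def items(self) -> tuple[str, ...]:
        return self.config.vocab_spec.items

    def item_probs(self, dx: str, shrink_applied: bool, site: str) -> np.ndarray:
        """Item distribution for a letter of content class ``dx``."""
        vocab = self.config.vocab_spec
        w = vocab.base_weights(site)
        exponent = self.config.ambiguity_shrink if shrink_applied else 1.0
        nb = len(vocab.background) + len(vocab.stopwords)
        ne = len(vocab.epilepsy_signal)
        if dx == "epilepsy":
            mults = np.fromiter(vocab.epilepsy_signal.values(), dtype=float, count=ne)
            w[nb : nb + ne] *= mults**exponent
        elif dx == "no_epilepsy":
            mults = np.fromiter(vocab.control_signal.values(), dtype=float)
            w[nb + ne :] *= mults**exponent
        else:
            raise ValueError(f"no generative item distribution for class {dx!r}")
        return w / w.sum()

    def log_likelihood_ratio(self, truth: LetterTruth) -> float:
        """Item-level log P(letter|epilepsy) - log P(letter|no_epilepsy)."""
        log_pe = np.log(self.item_probs("epilepsy", truth.shrink_applied, truth.site))
        log_pn = np.log(self.item_probs("no_epilepsy", truth.shrink_applied, truth.site))
        index = {item: i for i, item in enumerate(self.items)}
        llr = 0.0
        for item, count in truth.item_counts.items():
            i = index[item]
            llr += count * (log_pe[i] - log_pn[i])
        return llr


@dataclass(frozen=True)
class OracleEstimate:
    """Monte-Carlo estimate of the Bayes-optimal accuracy, with its SE."""

    accuracy: float
    se: float
    n_mc: int


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _compose_text(words: list[str], rng: np.random.Generator) -> str:
    """Light sentence scaffolding: capitalized sentence starts, periods."""
    out: list[str] = []
    i = 0
    n = len(words)
    while i < n:
        sent_len = min(int(rng.integers(6, 15)), n - i)
        sentence = list(words[i : i + sent_len])
        sentence[0] = sentence[0].capitalize()
        sentence[-1] = sentence[-1] + "."
        out.extend(sentence)
        i += sent_len
    return " ".join(out)


def _sample_letter_body(
    probs: np.ndarray,
    item_words: list[list[str]],
    target_words: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Draw whole items i.i.d. until the word count reaches the target."""
    n_items = len(item_words)
    counts = np.zeros(n_items, dtype=np.int64)
    words: list[str] = []
    while len(words) < target_words:
        batch = rng.choice(n_items, size=max(8, (target_words - len(words)) // 2 + 4), p=probs)
        for idx in batch:
            counts[idx] += 1
            words.extend(item_words[idx])
            if len(words) >= target_words:
                break
    return counts, words


def _generate(
    config: SynthConfig,
    rng: np.random.Generator,
    n: int,
    binary_only: bool = False,
    build_text: bool = True,
    id_prefix: str = "L",
) -> tuple[list[Letter], list[LetterTruth]]:
    vocab = config.vocab_spec
    items = vocab.items
    item_words = [item.split() for item in items]
    truth_proto = GroundTruth(config, [])
    # Cache the (class, shrink, site) -> probability vector table.
    prob_cache: dict[tuple[str, bool, str], np.ndarray] = {}

    def probs_for(dx: str, shrink: bool, site: str) -> np.ndarray:
        key = (dx, shrink, site)
        if key not in prob_cache:
            prob_cache[key] = truth_proto.item_probs(dx, shrink, site)
        return prob_cache[key]

    letters: list[Letter] = []
    truths: list[LetterTruth] = []
    width = max(4, len(str(n)))
    dx_levels = ("epilepsy", "no_epilepsy", "unclear")
    site_levels = ("site_A", "site_B")
    for k in range(n):
        site = site_levels[int(rng.random() >= config.site_props[0])]
        while True:
            final_dx = dx_levels[rng.choice(3, p=np.asarray(config.final_dx_props))]
            if not (binary_only and final_dx == "unclear"):
                break
        if final_dx == "unclear":
            initial_dx = "unclear"
        else:
            initial_dx = "unclear" if rng.random() < config.p_initial_unclear else final_dx
        shrink_applied = initial_dx == "unclear" and config.ambiguity_shrink < 1.0
        if final_dx == "unclear":
            content_class = "epilepsy" if rng.random() < 0.5 else "no_epilepsy"
        else:
            content_class = final_dx
        sex = "male" if rng.random() < config.p_male else "female"
        age = float(np.clip(rng.lognormal(math.log(4.5), 0.9), 1 / 12, 17.8))
        target_words = config.length_model.sample(rng)
        probs = probs_for(content_class, shrink_applied, site)
        counts, words = _sample_letter_body(probs, item_words, target_words, rng)
        text = _compose_text(words, rng) if build_text else " ".join(words)
        letter_id = f"{id_prefix}{k:0{width}d}"
        letters.append(
            Letter(
                id=letter_id,
                site=site,
                anamnesis_text=text,
                sex=sex,
                age_years=round(age, 2),
                initial_dx=initial_dx,
                final_dx=final_dx,
            )
        )
        truths.append(
            LetterTruth(
                id=letter_id,
                content_class=content_class,
                shrink_applied=shrink_applied,
                site=site,
                item_counts={items[i]: int(c) for i, c in enumerate(counts) if c > 0},
            )
        )
    return letters, truths


def generate_corpus(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a seeded synthetic corpus; identical seeds give identical
    corpora byte for byte."""
    rng = np.random.default_rng(config.seed)
    letters, truths = _generate(config, rng, config.n_letters)
    corpus = Corpus(tuple(letters), provenance=f"synthetic seed={config.seed}")
    return corpus, GroundTruth(config, truths)


def oracle_bayes_accuracy(
    config: SynthConfig, n_mc: int = 2000, seed: int | None = None
) -> OracleEstimate:
    """Monte-Carlo Bayes-optimal accuracy on the binary task.

    Generates ``n_mc`` letters with a definitive final diagnosis and
    classifies each by the exact generative posterior log-odds (class
    priors conditioned on a definitive diagnosis, plus the item-count
    log-likelihood ratio under the letter's own generative parameters).
    No trained classifier can beat this rate except by sampling luck.
    """
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100: smaller estimates are too noisy")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    letters, truths = _generate(config, rng, n_mc, binary_only=True, build_text=False, id_prefix="M")
    gt = GroundTruth(config, truths)
    pe, pn = config.final_dx_props[0], config.final_dx_props[1]
    log_prior_ratio = math.log(pe / pn)
    correct = 0
    for letter, truth in zip(letters, truths):
        score = log_prior_ratio + gt.log_likelihood_ratio(truth)
        predicted = "epilepsy" if score > 0 else "no_epilepsy"
        correct += predicted == letter.final_dx
    acc = correct / n_mc
    se = math.sqrt(max(acc * (1.0 - acc), 1e-12) / n_mc)
    return OracleEstimate(accuracy=acc, se=se, n_mc=n_mc)


def length_statistics(corpus: Corpus) -> dict[str, float]:
    """Min/max/median/mean whitespace word counts of a corpus."""
    if len(corpus) == 0:
        raise ValueError("length_statistics of an empty corpus")
    counts = np.array([letter.word_count for letter in corpus], dtype=float)
    return {
        "min": float(counts.min()),
        "max": float(counts.max()),
        "median": float(np.median(counts)),
        "mean": float(counts.mean()),
    }


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Serialize per-letter ground truth as JSONL (one letter per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for truth in gt.letters:
            fh.write(
                json.dumps(
                    {
                        "id": truth.id,
                        "content_class": truth.content_class,
                        "shrink_applied": truth.shrink_applied,
                        "site": truth.site,
                        "item_counts": truth.item_counts,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    return path


def read_ground_truth(path: str | Path, config: SynthConfig) -> GroundTruth:
    path = Path(path)
    truths = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                truths.append(
                    LetterTruth(
                        id=rec["id"],
                        content_class=rec["content_class"],
                        shrink_applied=rec["shrink_applied"],
                        site=rec["site"],
                        item_counts={k: int(v) for k, v in rec["item_counts"].items()},
                    )
                )
    return GroundTruth(config, truths)
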