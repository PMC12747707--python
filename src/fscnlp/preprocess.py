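"""Text preprocessing for the n-gram classifier arm.

The pipeline follows a fixed order: tokenize -> clean + lowercase ->
n-gram generation (max n = 2 by default) -> stopword removal.  Stopwords are
removed *after* n-grams are generated so that informative bigrams built from
stopwords can be retained selectively: ``no_fever`` survives even though
``no`` and ``fever`` are individually stopwords, and pronoun-noun phrases
like ``her_mouth`` are kept because they describe observed semiology.

Retention is expressed as three explicit mechanisms, each configurable:

* a bigram whitelist,
* a set of first tokens (negations: *geen*, *niet*, ...) that always keep
  their bigram,
* pronoun + clinical-noun pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

from .corpus_io import Corpus

_URL_RE = re.compile(r"^[\"'(\[]*(?:https?://|www\.)\S+$", re.IGNORECASE)
# Word = letters/digits (unicode, diacritics preserved), optionally joined by
# internal hyphens or apostrophes; leading/trailing punctuation is dropped.
_WORD_RE = re.compile(r"[^\W_]+(?:[-'][^\W_]+)*", re.UNICODE)
_HAS_ALNUM_RE = re.compile(r"[^\W_]", re.UNICODE)
_NUMERIC_RE = re.compile(r"^\d+([.,]\d+)?$")


def _load_wordlist(name: str) -> frozenset[str]:
    text = resources.files("fscnlp.data").joinpath(name).read_text(encoding="utf-8")
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class RetentionRules:
    """Which stopword-containing bigrams survive stopword removal."""

    always_keep_first_tokens: frozenset[str] = frozenset()
    whitelist_bigrams: frozenset[str] = frozenset()
    pronouns: frozenset[str] = frozenset()
    keep_pronoun_with: frozenset[str] = frozenset()


@dataclass(frozen=True)
class PreprocessConfig:
    nmax: int = 2
    bigram_connector: str = "_"
    stopword_list: frozenset[str] = frozenset()
    retention_rules: RetentionRules = field(default_factory=RetentionRules)
    strip_urls: bool = True
    strip_punct: bool = True
    drop_numeric: bool = False
    split_hyphens: bool = False

    def __post_init__(self) -> None:
        if self.nmax < 1:
            raise ValueError("nmax must be >= 1")
        if not self.bigram_connector:
            raise ValueError("bigram_connector must be non-empty")


@dataclass(frozen=True)
class NGramDoc:
    """The surviving unigram/bigram features of one letter, in order."""

    id: str
    features: tuple[str, ...]


# Default Dutch retention sets: negations that flip the clinical meaning of
# the following word, and pronouns worth keeping next to body-part /
# semiology nouns.
DUTCH_NEGATIONS = frozenset({"geen", "niet", "nooit", "zonder"})
DUTCH_PRONOUNS = frozenset(
    {"haar", "zijn", "hij", "zij", "ze", "hem", "het", "hun", "mijn", "uw", "ons", "je", "u", "me", "mij"}
)
DUTCH_CLINICAL_NOUNS = frozenset(
    {"mond", "ogen", "oog", "arm", "armen", "been", "benen", "hoofd", "lichaam", "tong", "spraak", "hand", "handen"}
)

ENGLISH_NEGATIONS = frozenset({"no", "not", "never", "without"})
ENGLISH_PRONOUNS = frozenset({"her", "his", "she", "he", "it", "their", "my", "your"})
ENGLISH_CLINICAL_NOUNS = frozenset(
    {"mouth", "eyes", "eye", "arm", "arms", "leg", "legs", "head", "body", "tongue", "speech", "hand", "hands"}
)


def default_dutch_config(**overrides) -> PreprocessConfig:
    """Preprocessing configuration with the frozen Dutch stopword list."""
    cfg = PreprocessConfig(
        stopword_list=_load_wordlist("stopwords_nl.txt"),
        retention_rules=RetentionRules(
            always_keep_first_tokens=DUTCH_NEGATIONS,
            pronouns=DUTCH_PRONOUNS,
            keep_pronoun_with=DUTCH_CLINICAL_NOUNS,
        ),
    )
    return replace(cfg, **overrides) if overrides else cfg


def default_english_config(**overrides) -> PreprocessConfig:
    cfg = PreprocessConfig(
        stopword_list=_load_wordlist("stopwords_en.txt"),
        retention_rules=RetentionRules(
            always_keep_first_tokens=ENGLISH_NEGATIONS,
            pronouns=ENGLISH_PRONOUNS,
            keep_pronoun_with=ENGLISH_CLINICAL_NOUNS,
        ),
    )
    return replace(cfg, **overrides) if overrides else cfg


def tokenize(text: str, split_hyphens: bool = False) -> list[str]:
    """Split text into word tokens on whitespace and punctuation boundaries.

    Intra-word hyphens, apostrophes and diacritics are preserved; URLs
    survive tokenization as single tokens (they are removed later, during
    cleaning).  Pure-punctuation chunks yield no token.
    """
    tokens: list[str] = []
    for chunk in text.split():
        if _URL_RE.match(chunk):
            tokens.append(chunk.lstrip("\"'([").rstrip(".,;:!?\"')]"))
            continue
        words = _WORD_RE.findall(chunk)
        if split_hyphens:
            words = [part for w in words for part in w.split("-")]
        tokens.extend(words)
    return tokens


def clean_and_lowercase(
    tokens: Sequence[str],
    strip_urls: bool = True,
    strip_punct: bool = True,
    drop_numeric: bool = False,
) -> list[str]:
    """Drop punctuation/symbol/URL tokens and lowercase the rest.

    Numeric tokens (ages, frequencies) are retained by default.  The
    operation is idempotent.
    """
    out: list[str] = []
    for tok in tokens:
        if strip_urls and _URL_RE.match(tok):
            continue
        if strip_punct and not _HAS_ALNUM_RE.search(tok):
            continue
        if drop_numeric and _NUMERIC_RE.match(tok):
            continue
        out.append(tok.lower())
    return out


def generate_ngrams(tokens: Sequence[str], config: PreprocessConfig) -> list[str]:
    """All unigrams in order, then adjacent n-grams up to ``config.nmax``.

    Bigrams are rendered with the connector, e.g. ``no_fever``.  For
    ``nmax=2`` the output length is ``len(tokens) + max(0, len(tokens)-1)``.
    """
    features = list(tokens)
    for n in range(2, config.nmax + 1):
        features.extend(
            config.bigram_connector.join(tokens[i : i + n])
            for i in range(len(tokens) - n + 1)
        )
    return features


def _keep_multigram(parts: Sequence[str], feature: str, config: PreprocessConfig) -> bool:
    stop = config.stopword_list
    rules = config.retention_rules
    if not any(p in stop for p in parts):
        return True
    if feature in rules.whitelist_bigrams:
        return True
    if parts[0] in rules.always_keep_first_tokens:
        return True
    if len(parts) == 2:
        a, b = parts
        if (a in rules.pronouns and b in rules.keep_pronoun_with) or (
            b in rules.pronouns and a in rules.keep_pronoun_with
        ):
            return True
    return False


def remove_stopwords_postngram(
    features: Sequence[str], config: PreprocessConfig
) -> list[str]:
    """Stopword removal applied after n-gram generation.

    A unigram is dropped iff it is a stopword.  An n-gram containing a
    stopword constituent is dropped unless a retention rule applies
    (whitelist, negation-first, or pronoun + clinical noun).
    """
    out: list[str] = []
    connector = config.bigram_connector
    for feature in features:
        if connector in feature:
            parts = feature.split(connector)
            if _keep_multigram(parts, feature, config):
                out.append(feature)
        elif feature not in config.stopword_list:
            out.append(feature)
    return out


def preprocess_text(text: str, config: PreprocessConfig) -> list[str]:
    """Full pipeline: tokenize, clean, lowercase, n-grams, stopword removal."""
    tokens = tokenize(text, split_hyphens=config.split_hyphens)
    tokens = clean_and_lowercase(
        tokens,
        strip_urls=config.strip_urls,
        strip_punct=config.strip_punct,
        drop_numeric=config.drop_numeric,
    )
    return remove_stopwords_postngram(generate_ngrams(tokens, config), config)


def preprocess_corpus(corpus: Corpus, config: PreprocessConfig) -> list[NGramDoc]:
    """Map every letter to exactly one :class:`NGramDoc` (order preserved)."""
    return [
        NGramDoc(id=letter.id, features=tuple(preprocess_text(letter.anamnesis_text, config)))
        for letter in corpus
    ]
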