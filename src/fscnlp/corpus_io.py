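"""Reading, validating, filtering and writing letter corpora.

A *letter* is the free-text clinical-history narrative (anamnesis) of one
child referred to a first seizure clinic, together with minimal metadata:
referring site, sex, age at first seizure, and the diagnosis assigned at the
first visit (``initial_dx``) and after follow-up (``final_dx``).  Diagnoses
take three values: ``epilepsy``, ``no_epilepsy`` and ``unclear``.

Corpora are serialized as JSONL (canonical: letters contain commas and
newlines) or CSV; both round-trip field-for-field.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

SITES = ("site_A", "site_B")
SEXES = ("male", "female")
DIAGNOSES = ("epilepsy", "no_epilepsy", "unclear")
BINARY_DIAGNOSES = ("epilepsy", "no_epilepsy")

#: Columns/keys every serialized letter record must carry.
REQUIRED_FIELDS = (
    "id",
    "site",
    "anamnesis_text",
    "sex",
    "age_years",
    "initial_dx",
    "final_dx",
)


class CorpusValidationError(ValueError):
    """A letter or corpus violates a domain invariant."""


class SchemaError(CorpusValidationError):
    """A serialized corpus is missing required columns or keys."""


@dataclass(frozen=True)
class Letter:
    """One anamnesis letter with its metadata labels."""

    id: str
    site: str
    anamnesis_text: str
    sex: str
    age_years: float
    initial_dx: str
    final_dx: str

    def __post_init__(self) -> None:
        if not str(self.id):
            raise CorpusValidationError("letter id must be non-empty")
        if self.site not in SITES:
            raise CorpusValidationError(
                f"letter {self.id!r}: invalid site {self.site!r} (expected one of {SITES})"
            )
        if self.sex not in SEXES:
            raise CorpusValidationError(
                f"letter {self.id!r}: invalid sex {self.sex!r} (expected one of {SEXES})"
            )
        for field_name in ("initial_dx", "final_dx"):
            value = getattr(self, field_name)
            if value not in DIAGNOSES:
                raise CorpusValidationError(
                    f"letter {self.id!r}: invalid {field_name} {value!r} "
                    f"(expected one of {DIAGNOSES})"
                )
        if not self.anamnesis_text.strip():
            raise CorpusValidationError(f"letter {self.id!r}: empty anamnesis text")
        if self.age_years < 0:
            raise CorpusValidationError(
                f"letter {self.id!r}: negative age {self.age_years}"
            )

    @property
    def word_count(self) -> int:
        """Whitespace-delimited token count of the anamnesis text."""
        return len(self.anamnesis_text.split())


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of letters with pairwise-distinct ids."""

    letters: tuple[Letter, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "letters", tuple(self.letters))
        seen: set[str] = set()
        dupes: list[str] = []
        for letter in self.letters:
            if letter.id in seen:
                dupes.append(letter.id)
            seen.add(letter.id)
        if dupes:
            raise CorpusValidationError(f"duplicate letter ids: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.letters)

    def __iter__(self) -> Iterator[Letter]:
        return iter(self.letters)

    def __getitem__(self, i: int) -> Letter:
        return self.letters[i]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(letter.id for letter in self.letters)

    def by_id(self, letter_id: str) -> Letter:
        for letter in self.letters:
            if letter.id == letter_id:
                return letter
        raise KeyError(letter_id)

    def subset(self, ids: Iterable[str], provenance: str | None = None) -> "Corpus":
        """Letters with the given ids, in corpus order."""
        wanted = set(ids)
        return Corpus(
            tuple(l for l in self.letters if l.id in wanted),
            provenance if provenance is not None else self.provenance,
        )


def _letter_from_record(record: dict, where: str) -> Letter:
    missing = [k for k in REQUIRED_FIELDS if k not in record or record[k] is None]
    if missing:
        raise SchemaError(f"{where}: missing required field(s) {missing}")
    try:
        age = float(record["age_years"])
    except (TypeError, ValueError) as exc:
        raise CorpusValidationError(
            f"{where}: age_years {record['age_years']!r} is not numeric"
        ) from exc
    try:
        return Letter(
            id=str(record["id"]),
            site=str(record["site"]),
            anamnesis_text=str(record["anamnesis_text"]),
            sex=str(record["sex"]),
            age_years=age,
            initial_dx=str(record["initial_dx"]),
            final_dx=str(record["final_dx"]),
        )
    except CorpusValidationError as exc:
        raise CorpusValidationError(f"{where}: {exc}") from None


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unknown corpus format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer corpus format from suffix {suffix!r}")


def read_corpus(path: str | Path, format: str | None = None, provenance: str = "") -> Corpus:
    """Read and validate a corpus from a JSONL or CSV file.

    Rows with invalid enum values or empty text raise
    :class:`CorpusValidationError` naming the offending row; a missing column
    raises :class:`SchemaError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    letters: list[Letter] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                record = json.loads(line)
                letters.append(_letter_from_record(record, f"{path.name} line {lineno}"))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [k for k in REQUIRED_FIELDS if k not in header]
            if missing:
                raise SchemaError(f"{path.name}: missing required column(s) {missing}")
            for rowno, record in enumerate(reader, start=2):
                letters.append(_letter_from_record(record, f"{path.name} row {rowno}"))
    return Corpus(tuple(letters), provenance=provenance)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> Path:
    """Write a corpus so that :func:`read_corpus` recovers an equal corpus."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for letter in corpus:
                fh.write(json.dumps(asdict(letter), ensure_ascii=False) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(REQUIRED_FIELDS), quoting=csv.QUOTE_ALL)
            writer.writeheader()
            for letter in corpus:
                record = asdict(letter)
                record["age_years"] = repr(letter.age_years)
                writer.writerow(record)
    return path


def exclude_short_letters(
    corpus: Corpus, min_words: int = 20
) -> tuple[Corpus, list[tuple[str, int]]]:
    """Drop letters shorter than ``min_words`` whitespace words.

    Mirrors the exclusion of succinct single-sentence letters from model
    training.  Returns the retained corpus and a log of ``(id, word_count)``
    for every excluded letter; retained + logged always partition the input.
    The boundary is inclusive: a letter with exactly ``min_words`` words is
    retained.
    """
    if min_words < 1:
        raise ValueError("min_words must be >= 1")
    kept: list[Letter] = []
    log: list[tuple[str, int]] = []
    for letter in corpus:
        wc = letter.word_count
        if wc >= min_words:
            kept.append(letter)
        else:
            log.append((letter.id, wc))
    return Corpus(tuple(kept), provenance=corpus.provenance), log


def write_exclusion_log(log: Sequence[tuple[str, int]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "word_count"])
        writer.writerows(log)
    return path
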