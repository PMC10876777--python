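"""Core domain types for timed-transcript speech analysis.

A *timed transcript* is the word-level output of an ASR system: an ordered
sequence of spoken words, each with onset and offset times in seconds, and
(after annotation) a lemma, universal POS tag and universal dependency
relation. Cohorts of such transcripts, a spoken-corpus frequency lexicon and
a content-unit dictionary for the described picture are the inputs to every
downstream feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

GROUPS = ("PCA", "CN")
TASKS = ("picture", "job")

#: Universal POS tags considered content words: nouns, verbs, adjectives,
#: adverbs. AUX and PROPN are deliberately excluded (separate universal
#: classes).
CONTENT_UPOS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})

UNIVERSAL_UPOS = frozenset(
    {
        "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
        "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
    }
)


class ValidationError(ValueError):
    """An input violated a documented invariant."""


class FormatError(ValueError):
    """An external file did not match its documented schema."""


@dataclass
class TimedToken:
    """One spoken word with its onset/offset and optional annotation.

    Times are decimal seconds. ``lemma``, ``upos`` and ``deprel`` stay
    ``None`` until an annotator fills them; ``syllables`` is filled lazily by
    the feature layer.
    """

    text: str
    start: float
    end: float
    lemma: Optional[str] = None
    upos: Optional[str] = None
    deprel: Optional[str] = None
    syllables: Optional[int] = None

    def __post_init__(self) -> None:
        self.text = self.text.strip()
        if not self.text:
            raise ValidationError("token text is empty after whitespace stripping")
        if not (math.isfinite(self.start) and math.isfinite(self.end)):
            raise ValidationError(f"non-finite times for token {self.text!r}")
        if self.start < 0:
            raise ValidationError(
                f"negative start time {self.start} for token {self.text!r}"
            )
        if self.end < self.start:
            raise ValidationError(
                f"end {self.end} < start {self.start} for token {self.text!r}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def is_annotated(self) -> bool:
        return self.lemma is not None and self.upos is not None and self.deprel is not None


@dataclass
class TranscriptSample:
    """One participant x task utterance sequence with its group label."""

    participant_id: str
    group: str
    task: str
    tokens: list[TimedToken] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be one of {TASKS}, got {self.task!r}")
        starts = [t.start for t in self.tokens]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValidationError(
                f"tokens of {self.participant_id!r} are not ordered by start time"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def is_annotated(self) -> bool:
        return all(t.is_annotated for t in self.tokens)

    def lemmas(self) -> list[str]:
        """Lower-cased lemma sequence; falls back to surface for unannotated tokens."""
        return [(t.lemma if t.lemma is not None else t.text).lower() for t in self.tokens]

    def with_tokens(self, tokens: Sequence[TimedToken]) -> "TranscriptSample":
        return replace(self, tokens=list(tokens))


class FrequencyLexicon:
    """Word -> raw occurrence count from a spoken reference corpus.

    Lookups are case-insensitive; counts are raw (not per-million), so the
    mean log-frequency feature is the mean natural log of these counts.
    """

    def __init__(self, counts: Mapping[str, int], corpus_total: int) -> None:
        if corpus_total <= 0:
            raise ValidationError("corpus_total must be positive")
        folded: dict[str, int] = {}
        for word, count in counts.items():
            if count < 1:
                raise ValidationError(f"non-positive count {count} for word {word!r}")
            key = word.strip().lower()
            folded[key] = folded.get(key, 0) + int(count)
        self.counts = folded
        self.corpus_total = int(corpus_total)

    def __contains__(self, word: str) -> bool:
        return word.strip().lower() in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def count(self, word: str) -> int:
        return self.counts[word.strip().lower()]

    def log_count(self, word: str) -> float:
        """Natural log of the raw corpus count."""
        return math.log(self.count(word))


class ContentUnitDictionary:
    """Unit id -> variant forms, plus the designated theme unit.

    Forms are lower-cased lemma sequences; a multiword form is stored as a
    tuple of lemmas and matches consecutive lemmas in a transcript. Every
    form maps to exactly one unit.
    """

    def __init__(
        self,
        units: Mapping[str, Iterable[str]],
        theme_unit: str,
    ) -> None:
        self.units: dict[str, tuple[tuple[str, ...], ...]] = {}
        owner: dict[tuple[str, ...], str] = {}
        for unit_id, forms in units.items():
            parsed = []
            for form in forms:
                key = tuple(form.lower().split())
                if not key:
                    raise ValidationError(f"empty form under unit {unit_id!r}")
                if key in owner and owner[key] != unit_id:
                    raise ValidationError(
                        f"form {' '.join(key)!r} listed under both "
                        f"{owner[key]!r} and {unit_id!r}"
                    )
                owner[key] = unit_id
                parsed.append(key)
            self.units[unit_id] = tuple(parsed)
        if theme_unit not in self.units:
            raise ValidationError(f"theme unit {theme_unit!r} not among units")
        self.theme_unit = theme_unit

    def __len__(self) -> int:
        return len(self.units)

    def unit_ids(self) -> list[str]:
        return list(self.units)
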