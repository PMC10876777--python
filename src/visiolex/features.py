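"""Per-sample quantitative language features.

Four timing/lexical features plus the content-unit outputs make up the
feature vector that enters the group statistics and the diagnostic
classifier:

* **mean log word frequency** — mean natural log of the raw lexicon count
  over content-word tokens (nouns, verbs, adjectives, adverbs); higher
  values mean more common (less specific) vocabulary;
* **word utterance latency** — the silent gap preceding each word, from the
  previous word's offset to the word's onset, excluding the first word;
* **articulation rate** — syllables per second of speaking time only
  (pauses are excluded from the denominator, so latency and articulation
  are decoupled components of overall speech rate);
* **spatial relational ratio** — tokens bearing the dependency relation
  ``case`` (adpositions such as "under", "into") over total tokens.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import content_units as cu
from .annotation import TaggerInterface, annotate_sample, is_content_word
from .types import (
    ContentUnitDictionary,
    FrequencyLexicon,
    TranscriptSample,
    ValidationError,
)

logger = logging.getLogger(__name__)

_VOWEL_GROUP = re.compile(r"[aeiouy]+")


@dataclass
class FeatureVector:
    """All per-sample predictors, plus bookkeeping counts.

    ``None`` marks a feature that is undefined for the sample (e.g. the
    frequency mean of a sample with no in-lexicon content word); writers
    serialize it as a missing value.
    """

    participant_id: str
    group: str
    task: str
    mean_log_frequency: Optional[float]
    mean_utterance_latency: Optional[float]
    articulation_rate: Optional[float]
    relational_ratio: Optional[float]
    total_content_units: int
    theme_mentioned: int
    focus_mentioned: int
    n_tokens: int
    n_content_words: int
    oov_count: int


def count_syllables(word: str) -> int:
    """Orthographic syllable estimate: vowel groups (a,e,i,o,u,y), minus a
    silent final "e" when other groups exist, minimum 1."""
    w = re.sub(r"[^a-z]", "", word.lower())
    if not w:
        logger.warning("no alphabetic characters in %r; counting 1 syllable", word)
        return 1
    groups = _VOWEL_GROUP.findall(w)
    n = len(groups)
    if n > 1 and w.endswith("e") and groups[-1] == "e":
        n -= 1
    return max(n, 1)


def mean_log_frequency(
    sample: TranscriptSample,
    lexicon: FrequencyLexicon,
    by_types: bool = False,
    impute_oov: Optional[int] = None,
) -> tuple[Optional[float], int, int]:
    """Mean ln(corpus count) over content-word tokens.

    Out-of-vocabulary content words are excluded from the mean and counted;
    returns (value, n_content, oov). ``value`` is None when no in-lexicon
    content word exists. ``by_types`` averages each distinct lemma once
    instead of per occurrence; ``impute_oov`` assigns OOV words that count
    instead of excluding them (they stay counted in ``oov``).
    """
    if not sample.is_annotated:
        raise ValidationError(f"sample {sample.participant_id!r} is not annotated")
    logs = []
    n_content = 0
    oov = 0
    seen_types: set[str] = set()
    for token in sample.tokens:
        if not is_content_word(token):
            continue
        n_content += 1
        key = (token.lemma or token.text).lower()
        if by_types:
            if key in seen_types:
                continue
            seen_types.add(key)
        if key in lexicon:
            logs.append(lexicon.log_count(key))
        elif token.text.lower() in lexicon:
            logs.append(lexicon.log_count(token.text))
        else:
            oov += 1
            if impute_oov is not None:
                logs.append(math.log(impute_oov))
    value = float(np.mean(logs)) if logs else None
    return value, n_content, oov


def utterance_latencies(
    sample: TranscriptSample, aggregate: str = "mean"
) -> tuple[list[float], Optional[float]]:
    """Per-word onset latencies (silent gap before each word) and their
    per-sample aggregate (``"mean"`` by default, ``"median"`` optional).

    The first word contributes no latency (task-start time is uninformative).
    Negative raw gaps — ASR timestamp jitter — are clamped to 0 with a
    warning. Undefined (None aggregate) for samples with fewer than 2 tokens.
    """
    if aggregate not in ("mean", "median"):
        raise ValidationError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    tokens = sample.tokens
    if len(tokens) < 2:
        return [], None
    gaps = []
    for i in range(1, len(tokens)):
        raw = tokens[i].start - tokens[i - 1].end
        if raw < 0:
            logger.warning(
                "overlapping timestamps for %r token %d (gap %.3f); clamping to 0",
                sample.participant_id, i, raw,
            )
            raw = 0.0
        gaps.append(raw)
    agg = np.mean(gaps) if aggregate == "mean" else np.median(gaps)
    return gaps, float(agg)


def articulation_rate(sample: TranscriptSample) -> Optional[float]:
    """Syllables per second of speaking time (word durations only).

    Inter-word pauses are excluded from the denominator. Undefined when
    the summed word duration is zero.
    """
    total_duration = sum(t.duration for t in sample.tokens)
    if total_duration <= 0:
        return None
    total_syllables = sum(
        t.syllables if t.syllables is not None else count_syllables(t.text)
        for t in sample.tokens
    )
    return total_syllables / total_duration


def relational_ratio(sample: TranscriptSample) -> Optional[float]:
    """Proportion of tokens bearing the dependency relation ``case``."""
    if not sample.is_annotated:
        raise ValidationError(f"sample {sample.participant_id!r} is not annotated")
    if not sample.tokens:
        return None
    n_case = sum(1 for t in sample.tokens if t.deprel == "case")
    return n_case / len(sample.tokens)


def extract_features(
    sample: TranscriptSample,
    lexicon: FrequencyLexicon,
    cu_dictionary: ContentUnitDictionary,
    focus_unit: str,
) -> FeatureVector:
    """Assemble the full feature vector for one annotated sample.

    ``focus_unit`` designates the extra indicator predictor (the scene's
    most group-discriminating item, "fisherman" in the shipped picnic
    dictionary); the theme indicator comes from the dictionary itself.
    """
    if focus_unit not in cu_dictionary.units:
        raise ValidationError(f"focus unit {focus_unit!r} not in dictionary")
    freq, n_content, oov = mean_log_frequency(sample, lexicon)
    _, latency = utterance_latencies(sample)
    mentioned = cu.detect_content_units(sample, cu_dictionary)
    return FeatureVector(
        participant_id=sample.participant_id,
        group=sample.group,
        task=sample.task,
        mean_log_frequency=freq,
        mean_utterance_latency=latency,
        articulation_rate=articulation_rate(sample),
        relational_ratio=relational_ratio(sample),
        total_content_units=len(mentioned),
        theme_mentioned=int(cu_dictionary.theme_unit in mentioned),
        focus_mentioned=int(focus_unit in mentioned),
        n_tokens=len(sample.tokens),
        n_content_words=n_content,
        oov_count=oov,
    )


#: Predictor columns entering the diagnostic classifier, in canonical order.
PREDICTOR_COLUMNS = [
    "mean_log_frequency",
    "mean_utterance_latency",
    "relational_ratio",
    "total_content_units",
    "theme_mentioned",
    "focus_mentioned",
]


class TranscriptFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: TranscriptSample list -> feature DataFrame.

    Stateless apart from parameter validation; ``fit`` records the feature
    names. Unannotated samples are annotated with ``tagger`` (default: the
    deterministic fallback).

    Parameters
    ----------
    lexicon : FrequencyLexicon
    cu_dictionary : ContentUnitDictionary
    focus_unit : str
        Unit whose mention indicator is the sixth classifier predictor.
    tagger : TaggerInterface, optional
    """

    def __init__(
        self,
        lexicon: FrequencyLexicon = None,
        cu_dictionary: ContentUnitDictionary = None,
        focus_unit: str = "fisherman",
        tagger: TaggerInterface = None,
    ):
        self.lexicon = lexicon
        self.cu_dictionary = cu_dictionary
        self.focus_unit = focus_unit
        self.tagger = tagger

    def fit(self, X: Sequence[TranscriptSample], y=None):
        if self.lexicon is None or self.cu_dictionary is None:
            raise ValidationError("lexicon and cu_dictionary are required")
        self.feature_names_ = list(PREDICTOR_COLUMNS)
        return self

    def transform(self, X: Sequence[TranscriptSample]) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        rows = []
        for sample in X:
            if not sample.is_annotated:
                sample = annotate_sample(sample, self.tagger)
            rows.append(
                vars(extract_features(sample, self.lexicon, self.cu_dictionary, self.focus_unit))
            )
        return pd.DataFrame(rows)


def extract_cohort(
    samples: Sequence[TranscriptSample],
    lexicon: FrequencyLexicon,
    cu_dictionary: ContentUnitDictionary,
    focus_unit: str = "fisherman",
    tagger: TaggerInterface = None,
) -> pd.DataFrame:
    """Feature table for a cohort (thin wrapper over the transformer)."""
    return TranscriptFeatureExtractor(
        lexicon=lexicon, cu_dictionary=cu_dictionary,
        focus_unit=focus_unit, tagger=tagger,
    ).fit(samples).transform(samples)
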