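"""Content-unit detection and cohort mention matrices.

A content unit is a predefined correct-information item of the described
picture. Detection matches lower-cased lemma sequences against the unit
dictionary's variant forms (multiword forms match consecutive lemmas);
morphological variants and synonyms grouped under one unit count once,
and repeated mentions count once per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .types import ContentUnitDictionary, TranscriptSample, ValidationError


@dataclass
class MentionMatrix:
    """Binary participant x unit mention indicators with the group vector."""

    data: pd.DataFrame          # index: participant_id, columns: unit ids, 0/1
    groups: pd.Series           # aligned to rows, values in {"PCA", "CN"}

    @property
    def unit_ids(self) -> list[str]:
        return list(self.data.columns)

    def mention_proportions(self) -> pd.DataFrame:
        """Per-unit empirical mention probability by group."""
        return self.data.groupby(self.groups).mean().T


def detect_content_units(
    sample: TranscriptSample, cu_dict: ContentUnitDictionary
) -> set[str]:
    """Units whose variant forms occur in the sample's lemma sequence.

    Each unit appears at most once regardless of repetitions; multiword
    variants must match consecutive lemmas. An empty sample yields an
    empty set.
    """
    lemmas = sample.lemmas()
    found: set[str] = set()
    unigrams = set(lemmas)
    for unit_id, forms in cu_dict.units.items():
        for form in forms:
            if len(form) == 1:
                if form[0] in unigrams:
                    found.add(unit_id)
                    break
            else:
                k = len(form)
                if any(
                    tuple(lemmas[i : i + k]) == form
                    for i in range(len(lemmas) - k + 1)
                ):
                    found.add(unit_id)
                    break
    return found


def total_content_units(sample: TranscriptSample, cu_dict: ContentUnitDictionary) -> int:
    """Number of distinct units mentioned (bounded by the dictionary size)."""
    return len(detect_content_units(sample, cu_dict))


def theme_mentioned(sample: TranscriptSample, cu_dict: ContentUnitDictionary) -> int:
    """1 iff the designated theme unit (the scene's gist) is detected."""
    return int(cu_dict.theme_unit in detect_content_units(sample, cu_dict))


def mention_matrix(
    cohort: Sequence[TranscriptSample], cu_dict: ContentUnitDictionary
) -> MentionMatrix:
    """Binary mention matrix for a single-task cohort, rows in input order."""
    if not cohort:
        raise ValidationError("cohort is empty")
    tasks = {s.task for s in cohort}
    if len(tasks) > 1:
        raise ValidationError(f"cohort mixes tasks {sorted(tasks)}")
    ids = [s.participant_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate participant_id in cohort")
    unit_ids = cu_dict.unit_ids()
    rows = []
    for sample in cohort:
        mentioned = detect_content_units(sample, cu_dict)
        rows.append([int(u in mentioned) for u in unit_ids])
    data = pd.DataFrame(rows, index=pd.Index(ids, name="participant_id"), columns=unit_ids)
    groups = pd.Series([s.group for s in cohort], index=data.index, name="group")
    return MentionMatrix(data=data, groups=groups)
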