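"""Readers and writers for the external file formats.

Formats handled here:

* timed transcript JSON — the ASR-style word list with per-word start/end
  times in seconds (``"0.400s"`` duration strings are accepted and stripped);
* CoNLL-U annotation files (FORM/LEMMA/UPOS/DEPREL columns; punctuation
  nodes dropped, remaining tokens aligned positionally);
* frequency lexicon TSV with a ``# corpus_total=<int>`` comment line;
* content-unit dictionary JSON;
* the per-participant feature table CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .types import (
    ContentUnitDictionary,
    FormatError,
    FrequencyLexicon,
    TimedToken,
    TranscriptSample,
    ValidationError,
)

PathLike = Union[str, Path]


def _parse_seconds(value: object, where: str) -> float:
    """Parse a time field; accepts floats, ints, and ASR "1.300s" strings."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        stripped = value.strip()
        if stripped.endswith("s"):
            stripped = stripped[:-1]
        try:
            return float(stripped)
        except ValueError:
            pass
    raise FormatError(f"cannot parse time {value!r} in {where}")


def read_timed_transcript(
    path: PathLike,
    participant_id: str | None = None,
    group: str | None = None,
    task: str | None = None,
) -> TranscriptSample:
    """Read one timed transcript JSON file into a :class:`TranscriptSample`.

    Identity fields present in the file are used unless overridden by the
    keyword arguments.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(payload, dict) or "words" not in payload:
        raise FormatError(f"{path}: expected an object with a 'words' list")
    tokens = []
    for i, rec in enumerate(payload["words"]):
        if not isinstance(rec, dict) or "word" not in rec:
            raise FormatError(f"{path}: word record {i} lacks a 'word' field")
        try:
            tokens.append(
                TimedToken(
                    text=str(rec["word"]),
                    start=_parse_seconds(rec.get("start", 0.0), f"word record {i}"),
                    end=_parse_seconds(rec.get("end", 0.0), f"word record {i}"),
                    lemma=rec.get("lemma"),
                    upos=rec.get("upos"),
                    deprel=rec.get("deprel"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: token {i}: {exc}") from exc
    return TranscriptSample(
        participant_id=participant_id or payload.get("participant_id", path.stem),
        group=group or payload.get("group", "CN"),
        task=task or payload.get("task", "picture"),
        tokens=tokens,
    )


def write_timed_transcript(sample: TranscriptSample, path: PathLike) -> None:
    payload = {
        "participant_id": sample.participant_id,
        "group": sample.group,
        "task": sample.task,
        "words": [
            {
                "word": t.text,
                "start": t.start,
                "end": t.end,
                **({"lemma": t.lemma} if t.lemma is not None else {}),
                **({"upos": t.upos} if t.upos is not None else {}),
                **({"deprel": t.deprel} if t.deprel is not None else {}),
            }
            for t in sample.tokens
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_frequency_lexicon(path: PathLike) -> FrequencyLexicon:
    """Read a word<TAB>count lexicon TSV.

    The corpus total is taken from a leading ``# corpus_total=<int>`` comment
    line; duplicate words (after case folding) have their counts summed.
    """
    path = Path(path)
    corpus_total = None
    counts: dict[str, int] = {}
    with path.open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("corpus_total"):
                    try:
                        corpus_total = int(body.split("=", 1)[1].strip())
                    except (IndexError, ValueError) as exc:
                        raise FormatError(
                            f"{path}:{lineno}: unparsable corpus_total line"
                        ) from exc
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip().lower() for f in fields[:2]] != ["word", "count"]:
                    raise FormatError(f"{path}:{lineno}: expected header 'word\\tcount'")
                header_seen = True
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected word<TAB>count")
            word = fields[0]
            try:
                count = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count {fields[1]!r}") from exc
            if count < 1:
                raise ValidationError(f"{path}:{lineno}: non-positive count for {word!r}")
            key = word.strip().lower()
            counts[key] = counts.get(key, 0) + count
    if corpus_total is None:
        raise FormatError(f"{path}: missing '# corpus_total=<int>' line")
    return FrequencyLexicon(counts, corpus_total)


def write_frequency_lexicon(lexicon: FrequencyLexicon, path: PathLike) -> None:
    lines = [f"# corpus_total={lexicon.corpus_total}", "word\tcount"]
    lines += [f"{w}\t{c}" for w, c in sorted(lexicon.counts.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cu_dictionary(path: PathLike) -> ContentUnitDictionary:
    """Read a content-unit dictionary JSON.

    Schema: ``{"units": {unit_id: [form, ...]}, "theme_unit": unit_id}``;
    multiword forms are space-joined lemma sequences.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(payload, dict) or "units" not in payload or "theme_unit" not in payload:
        raise FormatError(f"{path}: expected keys 'units' and 'theme_unit'")
    return ContentUnitDictionary(payload["units"], payload["theme_unit"])


def write_cu_dictionary(cu_dict: ContentUnitDictionary, path: PathLike) -> None:
    payload = {
        "units": {uid: [" ".join(f) for f in forms] for uid, forms in cu_dict.units.items()},
        "theme_unit": cu_dict.theme_unit,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_conllu_annotation(path: PathLike) -> list[tuple[str, str, str, str]]:
    """Read (form, lemma, upos, deprel) rows from a CoNLL-U file.

    Punctuation nodes, multiword-token ranges and empty nodes are dropped;
    only the FORM, LEMMA, UPOS and DEPREL columns are used.
    """
    rows: list[tuple[str, str, str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise FormatError(f"{path}:{lineno}: expected >= 8 CoNLL-U columns")
        tok_id, form, lemma, upos, deprel = cols[0], cols[1], cols[2], cols[3], cols[7]
        if "-" in tok_id or "." in tok_id:
            continue  # multiword ranges / empty nodes carry no timing slot
        if upos == "PUNCT":
            continue
        rows.append((form, lemma, upos, deprel))
    return rows


def apply_conllu_annotation(sample: TranscriptSample, path: PathLike) -> TranscriptSample:
    """Attach CoNLL-U annotation to a sample by positional alignment.

    The CoNLL-U word count (after dropping punctuation) must equal the
    token count; a mismatch is an error, never a silent skip.
    """
    rows = read_conllu_annotation(path)
    if len(rows) != len(sample.tokens):
        raise ValidationError(
            f"annotation length {len(rows)} != token count {len(sample.tokens)} "
            f"for {sample.participant_id!r}"
        )
    tokens = [
        TimedToken(
            text=t.text, start=t.start, end=t.end,
            lemma=lemma, upos=upos, deprel=deprel, syllables=t.syllables,
        )
        for t, (_, lemma, upos, deprel) in zip(sample.tokens, rows)
    ]
    return sample.with_tokens(tokens)


FEATURE_COLUMNS = [
    "participant_id",
    "group",
    "task",
    "mean_log_frequency",
    "mean_utterance_latency",
    "articulation_rate",
    "relational_ratio",
    "total_content_units",
    "theme_mentioned",
    "focus_mentioned",
    "n_tokens",
    "n_content_words",
    "oov_count",
]


def write_feature_table(features: Sequence, path: PathLike) -> None:
    """Write feature vectors to CSV, one row per participant x task."""
    if not features:
        raise ValidationError("feature list is empty")
    frame = pd.DataFrame([vars(f) if not isinstance(f, dict) else f for f in features])
    frame = frame[[c for c in FEATURE_COLUMNS if c in frame.columns]]
    dupes = frame.duplicated(subset=["participant_id", "task"])
    if dupes.any():
        bad = frame.loc[dupes, ["participant_id", "task"]].iloc[0]
        raise ValidationError(
            f"duplicate feature row for ({bad['participant_id']!r}, {bad['task']!r})"
        )
    frame.to_csv(path, index=False)


def read_feature_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
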