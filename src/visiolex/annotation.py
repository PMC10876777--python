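"""Token annotation: lemma, universal POS, dependency relation.

The features only consume three labels per token, so annotation is
abstracted behind a pluggable :class:`TaggerInterface`. A full neural
pipeline (Stanza, spaCy) can be registered as a plug-in; the shipped
default is a deterministic lexicon-plus-suffix tagger that needs no model
download. Adpositions receive the dependency relation ``case`` — the
operationalization of spatial relational words ("under", "into", ...)
used throughout the feature layer.
"""

from __future__ import annotations

from typing import Callable, Protocol, Sequence

from .types import CONTENT_UPOS, TimedToken, TranscriptSample, ValidationError

Annotation = tuple[str, str, str]  # (lemma, upos, deprel)


class TaggerInterface(Protocol):
    """Anything that maps an ordered word list to equal-length annotations."""

    def annotate(self, words: Sequence[str]) -> list[Annotation]: ...


# ---------------------------------------------------------------------------
# Fallback lexicon tagger
# ---------------------------------------------------------------------------

# Adpositions: upos ADP, deprel "case" (the spatial-relational trigger).
_ADPOSITIONS = (
    "aboard about above across after against along amid among around at "
    "atop before behind below beneath beside besides between beyond by "
    "despite down during except for from in inside into like near of off "
    "on onto opposite out outside over past per since through throughout "
    "till to toward towards under underneath until unto up upon via with "
    "within without"
).split()

_DETERMINERS = (
    "a an the this that these those each every either neither some any no "
    "all both half several such what which whose another"
).split()

_PRONOUNS = (
    "i you he she it we they me him her us them my your his its our their "
    "mine yours hers ours theirs myself yourself himself herself itself "
    "ourselves themselves who whom something someone anything anyone "
    "nothing nobody everything everyone there"
).split()

# (surface, lemma) pairs for auxiliaries and copulas.
_AUXILIARIES = {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be",
    "be": "be", "been": "be", "being": "be",
    "have": "have", "has": "have", "had": "have", "having": "have",
    "do": "do", "does": "do", "did": "do",
    "will": "will", "would": "would", "shall": "shall", "should": "should",
    "can": "can", "could": "could", "may": "may", "might": "might",
    "must": "must", "ought": "ought",
}

_CCONJ = "and or but nor so yet".split()
_SCONJ = "if because although while whereas unless when whether that".split()
_PARTICLES = {"not": "not", "n't": "not", "'s": "'s"}
_INTERJECTIONS = "oh um uh hmm mm er ah well okay yeah yes no hi".split()

# Common adverbs kept explicit so they are not mis-suffixed.
_ADVERBS = (
    "very too quite rather just also then now here once again always never "
    "often sometimes soon still already almost maybe perhaps together away "
    "back even only really more most less least far how why where"
).split()

_NUMERALS = (
    "one two three four five six seven eight nine ten eleven twelve "
    "first second third"
).split()


def _build_closed_class() -> dict[str, Annotation]:
    entries: dict[str, Annotation] = {}
    for w in _ADPOSITIONS:
        entries[w] = (w, "ADP", "case")
    for w in _DETERMINERS:
        entries.setdefault(w, (w, "DET", "det"))
    for w in _PRONOUNS:
        entries.setdefault(w, (w, "PRON", "nsubj"))
    for w, lemma in _AUXILIARIES.items():
        entries.setdefault(w, (lemma, "AUX", "aux"))
    for w in _CCONJ:
        entries.setdefault(w, (w, "CCONJ", "cc"))
    for w in _SCONJ:
        entries.setdefault(w, (w, "SCONJ", "mark"))
    for w, lemma in _PARTICLES.items():
        entries.setdefault(w, (lemma, "PART", "advmod"))
    for w in _INTERJECTIONS:
        entries.setdefault(w, (w, "INTJ", "discourse"))
    for w in _ADVERBS:
        entries.setdefault(w, (w, "ADV", "advmod"))
    for w in _NUMERALS:
        entries.setdefault(w, (w, "NUM", "nummod"))
    return entries


CLOSED_CLASS: dict[str, Annotation] = _build_closed_class()

_ADJ_SUFFIXES = ("ful", "ous", "ive", "able", "ible", "al", "ish", "less", "est")
_NOUN_SUFFIXES = ("tion", "sion", "ness", "ment", "ship", "hood", "ism", "ist", "er", "or")


class FallbackTagger:
    """Deterministic lexicon + suffix tagger.

    Closed-class words come from a fixed ~200-entry lexicon; open-class
    words are tagged by orthographic suffix (``-ly`` -> ADV, ``-ing``/``-ed``
    -> VERB, adjectival and nominal suffixes, NOUN as the default). Lemmas
    strip regular inflection only. Intended for tests and offline runs;
    real analyses should plug a full tagger.
    """

    def annotate(self, words: Sequence[str]) -> list[Annotation]:
        return [self._tag(w) for w in words]

    @staticmethod
    def _lemmatize(word: str, upos: str) -> str:
        if upos == "VERB":
            if word.endswith("ing") and len(word) > 5:
                return word[:-3]
            if word.endswith("ed") and len(word) > 4:
                return word[:-2]
        if upos == "NOUN" and word.endswith("s") and not word.endswith("ss") and len(word) > 3:
            return word[:-1]
        return word

    def _tag(self, word: str) -> Annotation:
        w = word.strip().lower()
        if w in CLOSED_CLASS:
            return CLOSED_CLASS[w]
        if w.endswith("ly") and len(w) > 3:
            return (w, "ADV", "advmod")
        if w.endswith(("ing", "ed")) and len(w) > 4:
            upos = "VERB"
        elif w.endswith(_ADJ_SUFFIXES) and len(w) > 4:
            upos = "ADJ"
        elif w.endswith(_NOUN_SUFFIXES) and len(w) > 4:
            upos = "NOUN"
        else:
            upos = "NOUN"
        deprel = {"VERB": "root", "ADJ": "amod", "NOUN": "obj"}[upos]
        return (self._lemmatize(w, upos), upos, deprel)


class GoldTagger:
    """Pass-through tagger for samples that already embed gold annotation."""

    def annotate(self, words: Sequence[str]) -> list[Annotation]:
        raise ValidationError(
            "GoldTagger cannot annotate raw words; use it only on samples "
            "whose tokens already carry lemma/upos/deprel"
        )


TAGGER_REGISTRY: dict[str, Callable[[], object]] = {
    "fallback": FallbackTagger,
}


def register_tagger(name: str, factory: Callable[[], object]) -> None:
    """Register a tagger plug-in under ``name`` (used by the CLI --tagger flag)."""
    TAGGER_REGISTRY[name] = factory


def get_tagger(name: str):
    try:
        return TAGGER_REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown tagger {name!r}; registered: {sorted(TAGGER_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def annotate_sample(
    sample: TranscriptSample,
    tagger: TaggerInterface | None = None,
    overwrite: bool = False,
) -> TranscriptSample:
    """Return a copy of ``sample`` with every token annotated.

    Already-annotated samples are returned unchanged unless ``overwrite``.
    The tagger must return exactly one (lemma, upos, deprel) per word.
    """
    if not sample.tokens:
        raise ValidationError(f"sample {sample.participant_id!r} has no tokens")
    if sample.is_annotated and not overwrite:
        return sample
    if tagger is None:
        tagger = FallbackTagger()
    labels = tagger.annotate([t.text for t in sample.tokens])
    if len(labels) != len(sample.tokens):
        raise ValidationError(
            f"tagger returned {len(labels)} labels for {len(sample.tokens)} tokens"
        )
    tokens = [
        TimedToken(
            text=t.text, start=t.start, end=t.end,
            lemma=lemma, upos=upos, deprel=deprel, syllables=t.syllables,
        )
        for t, (lemma, upos, deprel) in zip(sample.tokens, labels)
    ]
    return sample.with_tokens(tokens)


def is_content_word(token: TimedToken) -> bool:
    """True iff the token is a noun, verb, adjective or adverb."""
    if token.upos is None:
        raise ValidationError(f"token {token.text!r} is not annotated")
    return token.upos in CONTENT_UPOS
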