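import pytest

from visiolex import (
    ContentUnitDictionary,
    FrequencyLexicon,
    TimedToken,
    TranscriptSample,
)


def make_sample(words, participant_id="p1", group="CN", task="picture", gap=0.1,
                duration=0.4, annotations=None):
    """Build a sample with evenly spaced words; annotations is an optional
    equal-length list of (lemma, upos, deprel)."""
    tokens = []
    t = 0.0
    for i, word in enumerate(words):
        ann = annotations[i] if annotations else (None, None, None)
        tokens.append(
            TimedToken(text=word, start=t, end=t + duration,
                       lemma=ann[0], upos=ann[1], deprel=ann[2])
        )
        t += duration + gap
    return TranscriptSample(participant_id=participant_id, group=group,
                            task=task, tokens=tokens)


def annotated(words_with_labels, **kwargs):
    """Sample from (word, lemma, upos, deprel) tuples."""
    words = [w[0] for w in words_with_labels]
    annotations = [(w[1], w[2], w[3]) for w in words_with_labels]
    return make_sample(words, annotations=annotations, **kwargs)


@pytest.fixture
def tiny_lexicon():
    return FrequencyLexicon(
        {"picnic": 403, "basket": 100, "tree": 1000, "dog": 150, "run": 250},
        corpus_total=2_345_269,
    )


@pytest.fixture
def tiny_cu_dict():
    return ContentUnitDictionary(
        {
            "picnic": ["picnic"],
            "girl": ["girl", "daughter"],
            "basket": ["basket", "picnic basket"],
            "fisherman": ["fisherman", "angler"],
        },
        theme_unit="picnic",
    )
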