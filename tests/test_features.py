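import math

import numpy as np
import pytest

from visiolex import (
    TimedToken,
    TranscriptSample,
    ValidationError,
    articulation_rate,
    count_syllables,
    extract_features,
    mean_log_frequency,
    relational_ratio,
    utterance_latencies,
)
from visiolex.features import TranscriptFeatureExtractor

from conftest import annotated, make_sample


class TestSyllables:
    @pytest.mark.parametrize(
        "word,expected",
        [
            ("picnic", 2),
            ("the", 1),
            ("beautiful", 3),
            ("basket", 2),
            ("tree", 1),
            ("fisherman", 3),
            ("time", 1),      # silent final e
            ("a", 1),
            ("rhythm", 1),    # y as the only vowel group
        ],
    )
    def test_orthographic_counts(self, word, expected):
        assert count_syllables(word) == expected

    def test_no_alphabetic_characters_counts_one(self):
        assert count_syllables("1234") == 1


class TestMeanLogFrequency:
    def test_single_content_word(self, tiny_lexicon):
        sample = annotated([("picnic", "picnic", "NOUN", "obj")])
        value, n, oov = mean_log_frequency(sample, tiny_lexicon)
        assert value == pytest.approx(math.log(403), abs=1e-9)
        assert (n, oov) == (1, 0)

    def test_mean_of_two_counts(self, tiny_lexicon):
        sample = annotated(
            [("basket", "basket", "NOUN", "obj"), ("tree", "tree", "NOUN", "obj")]
        )
        value, _, _ = mean_log_frequency(sample, tiny_lexicon)
        assert value == pytest.approx((math.log(100) + math.log(1000)) / 2)
        assert value == pytest.approx(5.7565, abs=1e-4)

    def test_all_function_words_undefined(self, tiny_lexicon):
        sample = annotated(
            [("the", "the", "DET", "det"), ("is", "be", "AUX", "aux")]
        )
        value, n, oov = mean_log_frequency(sample, tiny_lexicon)
        assert value is None and n == 0 and oov == 0

    def test_oov_excluded_and_counted(self, tiny_lexicon):
        sample = annotated(
            [("picnic", "picnic", "NOUN", "obj"),
             ("zyzzyva", "zyzzyva", "NOUN", "obj")]
        )
        value, n, oov = mean_log_frequency(sample, tiny_lexicon)
        assert value == pytest.approx(math.log(403))
        assert (n, oov) == (2, 1)

    def test_order_and_function_word_invariance(self, tiny_lexicon):
        content = [("basket", "basket", "NOUN", "obj"), ("dog", "dog", "NOUN", "obj")]
        padded = [("the", "the", "DET", "det")] + content[::-1]
        v1, _, _ = mean_log_frequency(annotated(content), tiny_lexicon)
        v2, _, _ = mean_log_frequency(annotated(padded), tiny_lexicon)
        assert v1 == pytest.approx(v2)

    def test_unannotated_sample_rejected(self, tiny_lexicon):
        with pytest.raises(ValidationError):
            mean_log_frequency(make_sample(["dog"]), tiny_lexicon)

    def test_type_averaging_option(self, tiny_lexicon):
        # "tree" twice + "basket" once: token mean weights tree double
        sample = annotated([("tree", "tree", "NOUN", "obj"),
                            ("tree", "tree", "NOUN", "obj"),
                            ("basket", "basket", "NOUN", "obj")])
        tokens, _, _ = mean_log_frequency(sample, tiny_lexicon)
        types, _, _ = mean_log_frequency(sample, tiny_lexicon, by_types=True)
        assert tokens == pytest.approx((2 * math.log(1000) + math.log(100)) / 3)
        assert types == pytest.approx((math.log(1000) + math.log(100)) / 2)

    def test_oov_imputation_option(self, tiny_lexicon):
        sample = annotated([("picnic", "picnic", "NOUN", "obj"),
                            ("zyzzyva", "zyzzyva", "NOUN", "obj")])
        value, _, oov = mean_log_frequency(sample, tiny_lexicon, impute_oov=1)
        assert oov == 1
        assert value == pytest.approx((math.log(403) + 0.0) / 2)


def timed(words_times):
    tokens = [TimedToken(w, s, e) for w, s, e in words_times]
    return TranscriptSample(participant_id="p", group="CN", task="picture",
                            tokens=tokens)


class TestUtteranceLatency:
    def test_gaps_and_mean(self):
        sample = timed([("a", 0.00, 0.50), ("b", 0.80, 1.20), ("c", 1.20, 1.60)])
        gaps, mean = utterance_latencies(sample)
        assert gaps == pytest.approx([0.30, 0.00])
        assert mean == pytest.approx(0.15)

    def test_contiguous_words_zero_latency(self):
        sample = timed([("a", 0.0, 0.5), ("b", 0.5, 1.0), ("c", 1.0, 1.3)])
        gaps, mean = utterance_latencies(sample)
        assert mean == 0.0 and all(g == 0 for g in gaps)

    def test_overlap_clamped_to_zero(self):
        sample = timed([("a", 0.0, 0.6), ("b", 0.5, 1.0)])
        gaps, mean = utterance_latencies(sample)
        assert gaps == [0.0] and mean == 0.0

    def test_fewer_than_two_tokens_undefined(self):
        gaps, mean = utterance_latencies(timed([("a", 0.0, 0.5)]))
        assert gaps == [] and mean is None

    def test_median_aggregation_option(self):
        sample = timed([("a", 0.0, 0.5), ("b", 0.6, 1.0),
                        ("c", 1.1, 1.5), ("d", 3.5, 4.0)])
        _, mean = utterance_latencies(sample)
        _, median = utterance_latencies(sample, aggregate="median")
        assert median == pytest.approx(0.1)
        assert mean > median  # long outlier pause pulls the mean up
        with pytest.raises(ValidationError):
            utterance_latencies(sample, aggregate="mode")

    def test_speech_rate_decomposition(self):
        # elapsed time = speaking time + raw inter-word gap time (no overlaps)
        sample = timed([("a", 0.0, 0.4), ("b", 0.7, 1.3), ("c", 1.35, 2.0)])
        gaps, _ = utterance_latencies(sample)
        durations = sum(t.duration for t in sample.tokens)
        elapsed = sample.tokens[-1].end - sample.tokens[0].start
        assert elapsed == pytest.approx(durations + sum(gaps))


class TestArticulationRate:
    def test_two_word_rate(self):
        sample = timed([("picnic", 0.0, 0.5), ("basket", 0.7, 1.2)])
        assert articulation_rate(sample) == pytest.approx(4.0)  # 4 syl / 1.0 s

    def test_single_monosyllable(self):
        assert articulation_rate(timed([("dog", 0.0, 0.25)])) == pytest.approx(4.0)

    def test_zero_duration_undefined(self):
        assert articulation_rate(timed([("a", 0.5, 0.5)])) is None

    def test_pauses_excluded_from_denominator(self):
        fast = timed([("go", 0.0, 0.25), ("now", 0.30, 0.55)])
        slow_pause = timed([("go", 0.0, 0.25), ("now", 5.00, 5.25)])
        assert articulation_rate(fast) == pytest.approx(articulation_rate(slow_pause))


class TestRelationalRatio:
    def test_single_case_token_in_seven(self):
        from visiolex import annotate_sample

        sample = annotate_sample(
            make_sample(["i", "found", "the", "gem", "under", "my", "bed"])
        )
        assert relational_ratio(sample) == pytest.approx(1 / 7, abs=1e-4)

    def test_no_case_tokens_zero(self):
        sample = annotated([("dog", "dog", "NOUN", "nsubj"),
                            ("runs", "run", "VERB", "root")])
        assert relational_ratio(sample) == 0.0

    def test_single_case_token_upper_bound(self):
        sample = annotated([("under", "under", "ADP", "case")])
        assert relational_ratio(sample) == 1.0

    def test_invariant_under_duplication(self):
        labels = [("dog", "dog", "NOUN", "nsubj"),
                  ("under", "under", "ADP", "case"),
                  ("tree", "tree", "NOUN", "obl")]
        once = relational_ratio(annotated(labels))
        twice = relational_ratio(annotated(labels * 2))
        assert once == pytest.approx(twice)


class TestExtractFeatures:
    def picnic_sample(self):
        return annotated(
            [("there", "there", "PRON", "expl"),
             ("is", "be", "AUX", "aux"),
             ("a", "a", "DET", "det"),
             ("picnic", "picnic", "NOUN", "obj"),
             ("under", "under", "ADP", "case"),
             ("the", "the", "DET", "det"),
             ("tree", "tree", "NOUN", "obl")]
        )

    def test_composition_and_theme_flag(self, tiny_lexicon, tiny_cu_dict):
        fv = extract_features(self.picnic_sample(), tiny_lexicon, tiny_cu_dict,
                              focus_unit="fisherman")
        assert fv.theme_mentioned == 1
        assert fv.focus_mentioned == 0
        assert fv.total_content_units == 1
        assert fv.n_tokens == 7
        assert fv.relational_ratio == pytest.approx(1 / 7)

    def test_deterministic(self, tiny_lexicon, tiny_cu_dict):
        a = extract_features(self.picnic_sample(), tiny_lexicon, tiny_cu_dict, "fisherman")
        b = extract_features(self.picnic_sample(), tiny_lexicon, tiny_cu_dict, "fisherman")
        assert a == b

    def test_unknown_focus_unit_rejected(self, tiny_lexicon, tiny_cu_dict):
        with pytest.raises(ValidationError, match="focus"):
            extract_features(self.picnic_sample(), tiny_lexicon, tiny_cu_dict, "dragon")

    def test_transformer_matches_function(self, tiny_lexicon, tiny_cu_dict):
        samples = [self.picnic_sample()]
        table = TranscriptFeatureExtractor(
            lexicon=tiny_lexicon, cu_dictionary=tiny_cu_dict
        ).fit(samples).transform(samples)
        fv = extract_features(samples[0], tiny_lexicon, tiny_cu_dict, "fisherman")
        assert table.loc[0, "total_content_units"] == fv.total_content_units
        assert table.loc[0, "mean_log_frequency"] == pytest.approx(fv.mean_log_frequency)

    def test_transformer_get_params_round_trip(self, tiny_lexicon, tiny_cu_dict):
        ext = TranscriptFeatureExtractor(lexicon=tiny_lexicon,
                                         cu_dictionary=tiny_cu_dict)
        params = ext.get_params()
        assert params["focus_unit"] == "fisherman"
        ext.set_params(focus_unit="basket")
        assert ext.focus_unit == "basket"
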