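"""Synthetic two-group cohorts calibrated to published group statistics.

The study's raw recordings are not public, so this module generates
cohorts with the statistical structure the analysis assumes, at two
levels:

* **feature level** — draw each participant's feature vector directly
  from the group profile distributions;
* **transcript level** — emit template word streams (with gold
  annotation, per-word timestamps, and lexicon-stratified content words)
  constructed so that running the full extraction pipeline on them
  recovers the same profile distributions.

Calibration: each continuous feature is sampled from a distribution
whose *realized* mean and SD equal the profile values. Bounded features
use truncated normals whose parent parameters are numerically
moment-matched to the target. Word-onset latency is the exception: its
published moments have SD > mean on a nonnegative support, which no
left-truncated normal can realize, so latency uses a gamma distribution
moment-matched exactly (right-skewed, as pause data are). Mentions are
Bernoulli; per-unit probabilities anchor the theme and focus units and
interpolate the rest so expected totals match the profile mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .features import count_syllables
from .picnic import FOCUS_UNIT, THEME_UNIT, default_picnic_dictionary
from .types import (
    ContentUnitDictionary,
    FrequencyLexicon,
    TimedToken,
    TranscriptSample,
    ValidationError,
)


@dataclass
class GroupProfile:
    """Target feature moments and mention probabilities for one group."""

    freq_mean: float
    freq_sd: float
    latency_mean: float        # seconds, support >= 0
    latency_sd: float
    relational_mean: float     # proportion in [0, 1]
    relational_sd: float
    cu_total_mean: float       # content units, in [0, n_units]
    cu_total_sd: float
    theme_p: float             # P(mention theme unit)
    focus_p: float             # P(mention focus unit)
    articulation_mean: float   # syllables/second, support > 0
    articulation_sd: float

    def __post_init__(self) -> None:
        for p in (self.theme_p, self.focus_p):
            if not 0 <= p <= 1:
                raise ValidationError(f"mention probability {p} outside [0, 1]")
        for sd in (self.freq_sd, self.latency_sd, self.relational_sd,
                   self.cu_total_sd, self.articulation_sd):
            if sd < 0:
                raise ValidationError("profile SDs must be nonnegative")


@dataclass
class CohortConfig:
    """Cohort sizes, per-group profiles and the master seed."""

    n_per_group: tuple[int, int]          # (n patients, n controls)
    profiles: dict[str, GroupProfile]     # keys "PCA", "CN"
    seed: int
    n_units: int = 32

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValidationError("need at least 2 participants per group")
        if set(self.profiles) != {"PCA", "CN"}:
            raise ValidationError("profiles must be keyed by 'PCA' and 'CN'")


def default_paper_config(seed: int = 0, n_per_group: tuple[int, int] = (25, 29)) -> CohortConfig:
    """Picture-description cohort profiles from the published group tables.

    Patients: commoner words (higher log frequency), long skewed onset
    latencies, fewer relational words, far fewer content units, rare theme
    and focus mentions, slightly slower articulation. Controls the reverse.
    """
    pca = GroupProfile(
        freq_mean=6.50, freq_sd=0.53,
        latency_mean=0.38, latency_sd=0.54,
        relational_mean=0.08, relational_sd=0.03,
        cu_total_mean=7.20, cu_total_sd=5.63,
        theme_p=0.16, focus_p=0.08,
        articulation_mean=2.92, articulation_sd=0.60,
    )
    cn = GroupProfile(
        freq_mean=5.85, freq_sd=0.40,
        latency_mean=0.03, latency_sd=0.05,
        relational_mean=0.09, relational_sd=0.02,
        cu_total_mean=16.28, cu_total_sd=4.41,
        theme_p=0.90, focus_p=0.93,
        articulation_mean=3.14, articulation_sd=0.35,
    )
    return CohortConfig(n_per_group=n_per_group, profiles={"PCA": pca, "CN": cn}, seed=seed)


# ---------------------------------------------------------------------------
# Moment-matched samplers
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _truncnorm_params(mean: float, sd: float, low: float, high: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [low, high]-truncated normal has the target
    mean and SD. Raises if no such parent exists (e.g. SD too large for the
    support)."""

    def residual(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (low - mu) / sigma, (high - mu) / sigma
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol, info, ier, msg = optimize.fsolve(
        residual, x0=[mean, math.log(sd)], full_output=True
    )
    if ier != 1 or max(abs(r) for r in residual(sol)) > 1e-6 * max(sd, 1.0):
        raise ValidationError(
            f"cannot moment-match a truncated normal to mean={mean}, sd={sd} "
            f"on [{low}, {high}]"
        )
    return float(sol[0]), float(math.exp(sol[1]))


def sample_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    low: float, high: float, size: int,
) -> np.ndarray:
    """Truncated-normal draws whose realized mean/SD equal the targets."""
    if sd == 0:
        return np.full(size, mean)
    mu, sigma = _truncnorm_params(mean, sd, low, high)
    a, b = (low - mu) / sigma, (high - mu) / sigma
    return sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def sample_nonneg_skewed(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Gamma draws with exact target mean/SD (support >= 0, right-skewed).

    Used for onset latency, whose published SD exceeds its mean — a regime
    no normal truncated at zero can reach.
    """
    if mean <= 0 or sd == 0:
        return np.full(size, max(mean, 0.0))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def unit_mention_probabilities(
    profile: GroupProfile, unit_ids: list[str],
    theme_unit: str = THEME_UNIT, focus_unit: str = FOCUS_UNIT,
) -> dict[str, float]:
    """Per-unit Bernoulli probabilities: theme/focus anchored to the profile,
    the remaining units set to a common value so the expected total equals
    ``cu_total_mean``."""
    others = [u for u in unit_ids if u not in (theme_unit, focus_unit)]
    residual = profile.cu_total_mean - profile.theme_p - profile.focus_p
    p_other = min(max(residual / len(others), 0.0), 1.0) if others else 0.0
    probs = {u: p_other for u in others}
    probs[theme_unit] = profile.theme_p
    probs[focus_unit] = profile.focus_p
    return probs


# ---------------------------------------------------------------------------
# Feature-level generator
# ---------------------------------------------------------------------------

FEATURE_ORDER = [
    "mean_log_frequency",
    "mean_utterance_latency",
    "relational_ratio",
    "total_content_units",
    "theme_mentioned",
    "focus_mentioned",
    "articulation_rate",
]


def _draw_feature_row(rng: np.random.Generator, profile: GroupProfile, n_units: int) -> dict:
    freq = profile.freq_mean + profile.freq_sd * rng.standard_normal()
    latency = float(sample_nonneg_skewed(rng, profile.latency_mean, profile.latency_sd, 1)[0])
    relational = float(
        sample_truncated_normal(rng, profile.relational_mean, profile.relational_sd, 0.0, 1.0, 1)[0]
    )
    cu_total = int(round(float(
        sample_truncated_normal(
            rng, profile.cu_total_mean, profile.cu_total_sd, 0.0, float(n_units), 1
        )[0]
    )))
    theme = int(rng.random() < profile.theme_p)
    focus = int(rng.random() < profile.focus_p)
    articulation = float(
        sample_truncated_normal(
            rng, profile.articulation_mean, profile.articulation_sd, 0.0, math.inf, 1
        )[0]
    )
    return {
        "mean_log_frequency": freq,
        "mean_utterance_latency": latency,
        "relational_ratio": relational,
        "total_content_units": cu_total,
        "theme_mentioned": theme,
        "focus_mentioned": focus,
        "articulation_rate": articulation,
    }


def generate_feature_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Per-participant feature matrix and 0/1 labels (patients = 1).

    One child random stream per participant, split from the config seed, so
    the cohort is reproducible and participants are independent.
    """
    n_pca, n_cn = config.n_per_group
    streams = np.random.SeedSequence(config.seed).spawn(n_pca + n_cn)
    rows, ids, labels = [], [], []
    i = 0
    for group, n in (("PCA", n_pca), ("CN", n_cn)):
        profile = config.profiles[group]
        for j in range(n):
            rng = np.random.default_rng(streams[i])
            rows.append(_draw_feature_row(rng, profile, config.n_units))
            ids.append(f"{group}{j:03d}")
            labels.append(1 if group == "PCA" else 0)
            i += 1
    X = pd.DataFrame(rows, index=pd.Index(ids, name="participant_id"))[FEATURE_ORDER]
    y = pd.Series(labels, index=X.index, name="label")
    return X, y


# ---------------------------------------------------------------------------
# Transcript-level generator
# ---------------------------------------------------------------------------

_STRATUM_CONSONANTS = "bcdfghjklm"  # digit -> consonant; 587 -> "halaka"
UNIT_WORD_COUNT = 403               # ln(403) = 5.999, mid-range content word
_CASE_WORDS = ["under", "on", "in", "at", "near", "beside", "over", "behind"]
_FUNCTION_FILLERS = [
    ("the", "the", "DET", "det"),
    ("is", "be", "AUX", "aux"),
    ("and", "and", "CCONJ", "cc"),
    ("there", "there", "PRON", "expl"),
    ("it", "it", "PRON", "nsubj"),
]
_STRATUM_LO, _STRATUM_HI = 300, 900  # ln-count strata, hundredths of a nat


def _stratum_word(index: int) -> str:
    """Pronounceable synthetic word for the lexicon stratum with
    ln(count) = index/100."""
    return "".join(_STRATUM_CONSONANTS[int(d)] + "a" for d in str(index))


def default_lexicon() -> FrequencyLexicon:
    """Synthetic spoken-corpus lexicon at the scale of a 2.3M-word corpus.

    Content entries: 601 filler strata spanning ln(count) 3.00-9.00 in 0.01
    steps, plus every single-word content-unit variant at a mid-range count.
    """
    counts: dict[str, int] = {}
    for i in range(_STRATUM_LO, _STRATUM_HI + 1):
        counts[_stratum_word(i)] = max(int(round(math.exp(i / 100))), 1)
    for forms in default_picnic_dictionary().units.values():
        for form in forms:
            if len(form) == 1:
                counts[form[0]] = UNIT_WORD_COUNT
    for word in ["the", "and", "is", "there", "it"] + _CASE_WORDS:
        counts[word] = 50_000
    return FrequencyLexicon(counts, corpus_total=2_345_269)


def _filler_content_words(target_mean: float, k_units: int, n_fillers: int) -> list[str]:
    """Filler content words whose strata steer the sample's mean ln-count
    to ``target_mean`` given ``k_units`` unit words at the fixed unit count."""
    log_unit = math.log(UNIT_WORD_COUNT)
    total = target_mean * (k_units + n_fillers) - log_unit * k_units
    v = total / n_fillers
    index = int(round(v * 100))
    index = min(max(index, _STRATUM_LO), _STRATUM_HI)
    return [_stratum_word(index)] * n_fillers


def _build_transcript_tokens(
    rng: np.random.Generator,
    mentioned_units: list[str],
    cu_dict: ContentUnitDictionary,
    target_freq: float,
    target_latency: float,
    target_relational: float,
    target_articulation: float,
) -> list[TimedToken]:
    # (surface, lemma, upos, deprel) stream; gold annotation embedded so the
    # cohort is tagger-independent.
    words: list[tuple[str, str, str, str]] = []
    for unit in mentioned_units:
        lemma = next(f[0] for f in cu_dict.units[unit] if len(f) == 1)
        words.append((lemma, lemma, "NOUN", "obj"))
    k = len(mentioned_units)
    n_fillers = k + 4
    for w in _filler_content_words(target_freq, k, n_fillers):
        words.append((w, w, "NOUN", "obj"))
    n_content = len(words)
    n_total = max(int(round(n_content / 0.40)), n_content + 2)
    n_case = int(round(target_relational * n_total))
    n_func = n_total - n_content - n_case
    if n_func < 0:
        n_func = 2
        n_total = n_content + n_case + n_func
    for i in range(n_case):
        w = _CASE_WORDS[i % len(_CASE_WORDS)]
        words.append((w, w, "ADP", "case"))
    for i in range(n_func):
        words.append(_FUNCTION_FILLERS[i % len(_FUNCTION_FILLERS)])
    order = rng.permutation(len(words))
    tokens: list[TimedToken] = []
    t = 0.0
    for idx in order:
        surface, lemma, upos, deprel = words[idx]
        syl = count_syllables(surface)
        duration = syl / target_articulation
        start = t if not tokens else t + target_latency
        end = start + duration
        tokens.append(
            TimedToken(
                text=surface, start=round(start, 6), end=round(end, 6),
                lemma=lemma, upos=upos, deprel=deprel,
            )
        )
        t = end
    return tokens


def generate_transcript_cohort(
    config: CohortConfig,
    cu_dictionary: ContentUnitDictionary | None = None,
    lexicon: FrequencyLexicon | None = None,
    task: str = "picture",
) -> list[TranscriptSample]:
    """Template transcripts whose extracted features follow the config.

    Per participant: Bernoulli unit mentions (theme/focus anchored, others
    interpolated to the expected total), then a word stream assembled so
    that the extraction pipeline recovers the drawn per-sample frequency,
    latency, relational-ratio and articulation targets.
    """
    cu_dictionary = cu_dictionary if cu_dictionary is not None else default_picnic_dictionary()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    if len(cu_dictionary) < config.n_units:
        raise ValidationError(
            f"dictionary has {len(cu_dictionary)} units, config expects {config.n_units}"
        )
    unit_ids = cu_dictionary.unit_ids()[: config.n_units]
    n_pca, n_cn = config.n_per_group
    streams = np.random.SeedSequence(config.seed).spawn(n_pca + n_cn)
    samples: list[TranscriptSample] = []
    i = 0
    for group, n in (("PCA", n_pca), ("CN", n_cn)):
        profile = config.profiles[group]
        probs = unit_mention_probabilities(
            profile, unit_ids, cu_dictionary.theme_unit, FOCUS_UNIT
        )
        for j in range(n):
            rng = np.random.default_rng(streams[i])
            mentioned = [u for u in unit_ids if rng.random() < probs[u]]
            freq = profile.freq_mean + profile.freq_sd * rng.standard_normal()
            latency = float(
                sample_nonneg_skewed(rng, profile.latency_mean, profile.latency_sd, 1)[0]
            )
            relational = float(
                sample_truncated_normal(
                    rng, profile.relational_mean, profile.relational_sd, 0.0, 1.0, 1
                )[0]
            )
            articulation = float(
                sample_truncated_normal(
                    rng, profile.articulation_mean, profile.articulation_sd, 0.0, math.inf, 1
                )[0]
            )
            tokens = _build_transcript_tokens(
                rng, mentioned, cu_dictionary,
                freq, latency, relational, articulation,
            )
            samples.append(
                TranscriptSample(
                    participant_id=f"{group}{j:03d}", group=group, task=task, tokens=tokens
                )
            )
            i += 1
    return samples
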