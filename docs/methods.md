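# Methods

## The measurement model

The package treats connected speech as a behavioral readout of visuospatial
processing. Its inputs are word-timestamped transcripts: for each spoken
word, a surface form plus onset/offset times in seconds, as produced by
cloud ASR systems, optionally enriched with a lemma, a universal POS tag
and a universal-dependencies relation. Every downstream quantity is
defined per sample (one participant × one task):

- **Mean log word frequency.** For each content-word token (universal POS
  in {NOUN, VERB, ADJ, ADV} — AUX and PROPN are separate universal classes
  and are excluded), look up the raw count of its lower-cased lemma in a
  spoken-corpus lexicon and take the natural log; average over tokens. The
  natural log is deliberate: against a corpus of ~2.3 million words,
  ln(count) puts ordinary content words in the 5.5–7 range, the scale on
  which group means in this literature are reported; log10 would not.
  Out-of-vocabulary content words are excluded from the mean and reported
  in an `oov_count` (imputing them at count 1 would let a base-dependent
  floor dominate short samples); averaging is over tokens, not types, so
  repeating a common word moves the mean.
- **Word utterance latency.** gap_i = max(0, start_i − end_{i−1}) for
  i ≥ 2; the first word is excluded because time-to-start reflects task
  factors, not lexical retrieval. Negative raw gaps are ASR jitter and are
  clamped to zero with a warning. The per-sample statistic is the
  arithmetic mean of the gaps (a median option exists). Undefined below
  2 tokens.
- **Articulation rate.** Σ syllables / Σ (end − start), in syllables per
  second. The denominator is speaking time only: latency and articulation
  are the two separable components of overall speech rate, and collapsing
  them into words-per-minute would mix two mechanisms. Syllables come from
  a deterministic orthographic heuristic (vowel groups a,e,i,o,u,y, minus
  a silent final "e" when other groups exist, minimum 1); a pronunciation
  dictionary can be plugged in, but the heuristic keeps tests reproducible
  with no download.
- **Spatial relational ratio.** Tokens whose dependency relation is `case`
  divided by total tokens. This is an operationalization by syntactic
  relation, not by a curated spatial-word list: most `case` tokens in
  scene descriptions are spatial adpositions, but "of" and possessive
  markers also qualify. All `case` tokens are counted by default; a
  curated list can be supplied via the content-unit-style configuration if
  a user wants strictly spatial semantics.
- **Content units.** A dictionary maps unit ids to variant forms
  (lower-cased lemma sequences; multiword forms match consecutive lemmas).
  A unit counts once per sample regardless of repetitions, and synonym or
  morphological variants ("girl"/"daughter") count as one unit. Matching
  is exact on lemmas — no fuzzy matching, which would silently change
  counts. The shipped picnic dictionary has 32 units with "picnic" as the
  theme unit and "fisherman" as the default focus unit; the theme is an
  ordinary unit (it contributes to totals and is screened). Only five of
  its units are analysis-critical; the rest are plausible scene items, and
  users reproducing a particular instrument should supply their own
  dictionary JSON.

Transcript normalization is deliberately minimal: all ASR tokens are kept,
including filled pauses ("um"), because no principled exclusion list is
task-independent; users can pre-filter if their instrument demands it.

## Annotation

Features need only (lemma, upos, deprel) per token, so annotation is a
pluggable interface. The shipped fallback tagger is a fixed ~200-entry
closed-class lexicon (adpositions → ADP/`case`, determiners, pronouns,
auxiliaries, conjunctions) plus suffix heuristics for open-class words. It
is deterministic across runs and platforms, which is what the test suite
needs; it is not a replacement for a neural tagger on real data, and the
registry accepts any object with an `annotate(words) -> [(lemma, upos,
deprel)]` method. CoNLL-U files can supply gold annotation; punctuation
nodes are dropped (ASR output has none) and remaining rows must align
one-to-one with the token stream — a length mismatch is an error, never a
silent skip, because every ratio here is per word.

## Statistics

Group comparisons are Welch two-sample t-tests (unequal variances,
Satterthwaite df). The sign convention is t = (mean₂ − mean₁)/SE with the
patient group passed first, so patient-elevated features get negative t.
Sample SDs use the n−1 denominator throughout — required, e.g., to
reproduce SDs of binary mention variables from their proportions. The
summary-based route is the closed form; the vector route goes through
scipy's Welch implementation, and their exact agreement is a tested
invariant rather than an implementation identity.

The per-unit screen computes a point-biserial correlation (Pearson r of
the 0/1 group code against the 0/1 mention indicator, i.e. a phi
coefficient) per unit, with p from the t transformation on n−2 df.
Zero-variance units are reported as untestable rather than erroring the
table. The Bonferroni divisor defaults to the full instrument size (all 32
units) even when some columns are untestable: the threshold is a property
of the instrument, stays stable across cohorts, and is overridable.

## Classifier

A binary logistic regression on six predictors (frequency, latency,
relational ratio, content-unit total, theme indicator, focus indicator).
Two choices the classical description leaves open are made explicit:

- predictors are standardized within each training fold (binary
  indicators included), for scale-free comparability and so the ridge
  penalty is meaningful;
- a small ridge penalty (1e-3 on standardized coefficients) is always
  applied, because well-separated cohorts — exactly the regime this
  classifier targets — make the unpenalized MLE diverge; the penalty
  guarantees a unique finite optimum and perturbs non-separable fits
  negligibly (coefficients shift by O(ridge)).

Validation is leave-one-out: n refits (scaler and model both refit per
fold), held-out probabilities pooled, labels at a fixed 0.5 threshold.
Accuracy/precision/recall use the patient group as positive. AUC is
computed as pairwise concordance with ties at 1/2 on the pooled LOOCV
probabilities (one curve, one AUC); the ROC point set is the standard
threshold sweep.

## Synthetic cohorts and calibration

Real clinical recordings cannot ship, so the generator produces cohorts
with the published group-level structure, parameterized by a
`GroupProfile` per group (means/SDs of the five continuous features,
Bernoulli probabilities for theme and focus mentions) and a
`CohortConfig` (sizes, seed, unit count). The default configuration uses
the published picture-task values: patients (n=25) at frequency 6.50±0.53,
latency 0.38±0.54 s, relational 0.08±0.03, content units 7.20±5.63, theme
p=0.16, focus p=0.08, articulation 2.92±0.60 syl/s; controls (n=29) at
5.85±0.40, 0.03±0.05 s, 0.09±0.02, 16.28±4.41, p=0.90, p=0.93, 3.14±0.35.

Distributional choices:

- Bounded features (relational ratio on [0,1], unit totals on [0,32],
  articulation on [0,∞)) use truncated normals whose *parent* parameters
  are solved numerically so that the truncated distribution's realized
  mean and SD equal the profile values. Naive truncation at the profile
  parameters would bias the realized mean (e.g. unit totals 7.20±5.63
  truncated at 0 would realize a mean near 8.3) and recovery tests would
  measure the bias, not the pipeline.
- Latency uses a gamma distribution moment-matched exactly to the profile
  mean and SD. This is the one feature where a truncated normal *cannot*
  work: both groups' published latency SDs exceed their means, and a
  normal left-truncated at zero always has SD < mean. The published
  moments themselves say the latency distribution is heavily
  right-skewed, which gamma is.
- Unit totals are rounded to integers after drawing (adds variance 1/12,
  negligible against SDs of 4–6).
- Features are drawn independently within participant. The true
  within-subject covariance is unpublished, and inventing correlation
  structure would smuggle unverifiable assumptions into every downstream
  test; a correlation-matrix hook is the natural extension point.

The transcript-level generator closes the loop with the extraction code.
Per participant it draws per-sample targets from the same calibrated
distributions, then assembles a word stream that realizes them: mentioned
units are Bernoulli draws (theme and focus at their profile probabilities,
the other 30 units at a common interpolated probability so the *expected*
total equals the profile mean — so transcript-mode totals match the target
mean but have Bernoulli-sum variance, smaller than the published SD);
each mentioned unit contributes its canonical lemma; filler content words
are chosen from lexicon strata (601 synthetic words spanning ln-count
3.00–9.00 in 0.01 steps) so the sample's content-word mean log frequency
hits its target; `case`-tagged adpositions and non-content function
fillers are added so the relational ratio and a ~40% content density hold;
durations are syllables/target-rate and inter-word gaps are the target
latency, so extraction recovers both timing features exactly. Gold
annotation is embedded, making generated cohorts tagger-independent.
All randomness descends from one seed through per-participant spawned
streams, so cohorts are reproducible and order-independent.

What the generator does **not** emulate: natural prose (templates exercise
extraction contracts, not fluency), within-subject feature covariance,
per-unit salience differences among the 30 non-anchored units, ASR errors
and timestamp jitter, and per-sample latency dispersion (the gap is
constant within a sample; between-sample dispersion carries the profile
SD). Passing tests on synthetic cohorts therefore demonstrate the
pipeline's correctness and the discriminability implied by the published
group parameters — not performance on real recordings.

## Problem sizes in the shipped checks

Recovery checks run at n=200 per group (every profile mean recovered
within 2 SE end to end); classification and screen checks run 100 seeded
cohorts at the published n=(25,29). With those conditions the mean LOOCV
accuracy is ≈0.95 and mean AUC ≈0.99 — high, as expected given the large
published group separations, and slightly below the near-perfect figures
reported on real data, which is consistent with independence being a
conservative assumption about the predictors' joint structure. One
documented behavior of the screen: with independent mentions at the
published marginals, the theme unit's expected correlation (−0.74) lies
close enough to the focus unit's (−0.85) that the focus unit ranks
strongest-negative in only ~83% of cohorts at n=54, not ≳95%; resolving
that would require either excluding the theme from the screen or assuming
unpublished mention covariance, and the package does neither.

## Numerical notes and edge cases

- Undefined features (no in-lexicon content word, <2 tokens, zero speaking
  time) are `None`/NaN, flagged in QC output, and rejected by the
  classifier rather than imputed.
- Times accept ASR "1.300s" duration-string form; stored as float seconds
  (≥ ms precision).
- Token order within generated samples is a seeded permutation;
  detection is order-insensitive at the set level by construction.
- The Welch test refuses two zero-SD groups; the point-biserial refuses
  constant values or a single group; `|r|` is clipped to 1 before the
  t transform to guard rounding at perfect association.
- Logistic fits run to tol 1e-8 with an explicit convergence check; LOOCV
  agreement with a generic-optimizer oracle is tested to ~1e-4 in
  held-out probability.
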