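# Methods

## The measurement model

The package analyses two concurrent data streams for one participant at a
time.

**Passive stream.** During phone use, a screenshot is captured every 5
seconds; OCR reduces each to text blocks with per-block confidence in
[0, 1]. A screenshot therefore stands for one 5-second slot of phone use:
an hour contains at most 720 slots, and the fraction of an hour spent on
the phone is `count * 5 / 3600`. Days and hours are binned in the
participant's local time; each person carries one fixed UTC offset, and the
recorded offset of a timestamp defines its calendar day and hour. Duplicate
events inside one 5-second slot are collapsed with a warning.

**Active stream.** A signal-contingent EMA design: 6 prompts per day for 28
days, each delivered uniformly at random within one of six 2-hour windows
tiling a 12-hour block (default 09:00–21:00), answerable for 30 minutes
with one reminder at 15 minutes. Responses after expiry are invalid (they
are dropped on read, with a warning) because the compliance definition
rests on completed-within-protocol prompts. Likert items are coded 1–5;
composites are sums — ideation over 4 items (4–20), planning over 3 (3–15),
desire over 2 (2–10) — and a composite is missing when any constituent item
is missing (listwise per composite, no prorating).

## Text normalization and phrase matching

Normalization is: case reduction, removal of punctuation and digits
(tokens are the maximal runs of ASCII letters after lowercasing), then
lemmatization. The lemmatizer is a compact rule system — an
irregular-forms table plus suffix rules for plurals and -ing/-ed forms —
applied to a fixed point, so every lemma is its own lemma and the full
normalization is idempotent. Lexicons are stored pre-normalized through
the same normalizer, which makes matching invariant to which lemmatizer
produced a lexicon as long as text and lexicon share one normalizer. A
rule lemmatizer over-stems some rare English forms; for dictionary scoring
this is immaterial because both sides of the match pass through the same
rules.

Phrase matching scans the token stream left to right; at each position the
longest matching lexicon entry wins (ties broken lexicographically) and
consumes its tokens. This prevents a phrase and its sub-phrase ("end it
all" / "end") from double counting. Screens whose token stream contains a
full rendered EMA item wording (e.g. "I want to die") are removed before
suicide-related scoring so the survey's own text cannot inflate the scores;
one matched item phrase suffices. Consecutive identical screens are *not*
deduplicated by default — a static screen legitimately re-counts every 5
seconds of continued exposure — but a collapse option exists for
sensitivity analyses.

Daily dictionary scores are displayed as ratios, day count over the total
across the observation window, so persons with very different phone-use
volumes remain comparable; an all-zero series stays all-zero rather than
0/0. The ratio denominator is the sum over all days of the study window.

## EMA metrics

Compliance: overall = 100·completed/received; response-day compliance =
100·completed/(6·response days), where a response day is a calendar study
day with at least one completed response. Percentages are rounded half
away from zero to one decimal for reporting; raw values are kept
internally. High flags use the empirical 90th percentile with linear
interpolation between order statistics, and flag values *at or above* the
threshold, so a constant series flags everywhere (degenerate
distribution). Binary items collapse to day level by any-endorsement; a
day with responses and no endorsement is 0, a day with no responses is
missing — missingness is never zero-filled for EMA-derived columns, since
compliance gaps are themselves a finding.

## Profiles and smoothing

All per-day series join on (person, study day) into one table;
count-derived columns are zero-filled (an observed zero), EMA-derived
columns keep NaN. When a hospitalization is recorded, `relative_day` =
study day − first hospitalization day, so day 0 is the first
hospitalization day and the alignment is invertible.

Loess: locally weighted linear regression, degree 1, tricube weights
`(1 − (d/dmax)^3)^3` over the `ceil(span·n)` nearest neighbors (stable
argsort for ties), no robustness iterations, default span 0.75. The local
solve uses centered normal equations with a degenerate-spread guard that
falls back to the weighted mean. Degree-1 fitting reproduces constants and
straight lines exactly and commutes with affine transforms of y.

## The synthetic generator

The generator emulates the study conditions so that the analysis can be
demonstrated and validated without any real data:

- **Design**: 35 study days; 28 EMA days, 6 prompts/day in 2-hour windows
  over a 12-hour block from 09:00; crisis (first hospitalization day) on
  day 29 with a 4-day stay.
- **Usage**: sessions per day ~ Poisson (default mean 40), session starts
  drawn from hour-of-day intensity weights that increase across the waking
  day, session lengths exponential (default mean 6 min), screenshots every
  5 seconds within sessions, overlaps merged. The defaults target roughly
  4 hours of capture per day, between the two published case summaries
  (5.92 and 3.59 h/day). Phone use ramps up by 1.5× over the week before
  the crisis.
- **Text**: background pseudo-word vocabulary (500 words, built
  deterministically and excluding every lexicon token so background cannot
  match by accident), ~10 tokens/screen; each lexicon phrase is injected
  as a contiguous run at a uniform position with per-screen Poisson rate
  `r0 · m_d`; by default `m = 5` on the day before the crisis for the
  risk-factor and substance dictionaries, `m = 1` elsewhere. Block
  confidences come from a mixture placing a configurable share (default
  10%) below the 0.70 OCR cutoff. A share of screens carries a
  social-content probability (Beta-distributed, higher for "social"
  screens).
- **EMA**: per-prompt answer probability follows a logistic ramp from the
  baseline (default 0.60, a typical clinical-population compliance level)
  down to a floor of 0.10 starting three days before the crisis. Ordinal
  items discretize a latent severity trajectory that rises piecewise
  linearly to the crisis day; pain is Normal (default mean 74.4, SD 16.2,
  the published per-person summary, clipped to [0, 100]); binaries are
  Bernoulli; sleep items attach to the morning prompt only. Completion
  times are uniform within the 30-minute validity window.
- **Determinism**: all streams derive from one seed through independent
  child sequences; identical (config, seed) gives byte-identical outputs.

What the generator does **not** emulate: real OCR error text (confidence
is the only OCR artifact modeled), app-specific screen layouts, language
other than lowercase English renderings, non-stationary vocabularies,
within-day autocorrelation of EMA items, or notification failures
(prompts received always equals prompts scheduled). Passing recovery
tests therefore show the pipeline's correctness and sensitivity under the
assumed generative structure, not performance on real screen text.

## Problem sizes and validation choices

Recovery checks run at deliberately scaled-down usage volumes chosen once:

- Crisis-spike recovery uses 30 short sessions/day (~180 screens/day,
  ~1800 background tokens/day) over 100 seeds. Day-to-day screen volume
  must be reasonably stable for a per-screen rate spike to dominate the
  *count* ratio: with very few long sessions per day, exponential session
  lengths make daily volume so dispersed that a single long session on a
  background day can out-count the spike. Real screenome volumes
  (thousands of screens/day) are in the stable regime; the chosen
  configuration preserves that regime at a fraction of the volume.
- Compliance-decay detection runs the EMA generator alone over 200 seeds.
- End-to-end determinism runs the full pipeline twice at 12 sessions/day
  (~10k screens); the property does not depend on volume.

Numerical conventions: ratio conservation is exact up to 1e-12; the loess
fit is compared with an independent weighted least-squares solve at 1e-8;
percentile thresholds follow numpy's linear interpolation; reported
percentages round half away from zero to one decimal (63/138 → 45.7,
against a published 45.6 that may reflect truncation — both lie within the
0.1 reporting ambiguity).

## Known limitations

- The rule lemmatizer is intentionally small; applications with richer
  lexicons may plug in any callable `text -> [lemmas]` as the normalizer,
  provided lexicons are loaded through the same callable.
- App-category keywords over-match by design ("text" tags any screen
  containing the word); the keyword lists are configurable.
- One fixed UTC offset per person: daylight-saving transitions inside a
  study window are not modeled.
- Social-content probabilities are consumed, never produced; the upstream
  screen classifier is out of scope.
- Single-person analytics: multi-person studies iterate the pipeline per
  participant and concatenate profile tables.
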