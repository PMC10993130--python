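# screenome

Daily suicide-risk profiling from smartphone **screenomics** (high-frequency
screenshot text) and **ecological momentary assessment** (EMA) self-reports.

Passive sensing studies in computational psychiatry capture a participant's
phone screen every 5 seconds during use, OCR the text, and pair it with
signal-contingent EMA surveys (6 prompts/day in random 2-hour windows over a
12-hour block). This package implements the analysis layer of such a study:
it turns raw screenshot-text events and item-level EMA responses into
hospitalization-aligned per-day risk profiles. Because real data of this
kind are protected, a fully parameterized synthetic-participant generator is
included, so every stage is testable and demonstrable end to end.

## What it computes

- **Text normalization** — OCR blocks below a confidence threshold (default
  0.70) are dropped; text is lowercased, stripped of punctuation and digits,
  and lemmatized; screens that show the EMA survey itself are removed before
  suicide-lexicon scoring.
- **Lexicon scoring** — non-overlapping longest-first phrase matching of
  topic dictionaries (suicide, risk factors, crisis, substances) against
  normalized token streams. Daily scores are reported as ratios,
  `r_d = c_d / Σ_d c_d`, alongside raw counts; plus within-day hourly
  trajectories, top-*k* endorsed words, app-category tags (SMS / Meta
  keywords), and per-day sums of screen-level social-content probabilities.
- **EMA metrics** — compliance (overall = completed/received; response-day
  = completed/(6·days with ≥1 response)), composite momentary suicidal
  ideation (4 Likert items, range 4–20), planning (3 items, 3–15) and desire
  (2 items, 2–10), person-specific high flags (value ≥ empirical 90th
  percentile), binary risk-factor day series, and item summaries (n, mean,
  SD).
- **Phone use** — each screenshot is one 5-second slot, so an hour holds at
  most 720 and the use fraction of an hour is `count·5/3600` (360 screens =
  50%); day × hour matrices, mean hourly profiles, intensive-use hours
  (fraction > 0.5), and collection hours per day.
- **Profiles** — all daily series joined into one table per person-day,
  re-indexed so relative day 0 is the first hospitalization day, with loess
  (tricube-weighted local linear regression) trend smoothing.

## Worked example

```python
from screenome import SyntheticConfig, generate_person, pipeline

config = SyntheticConfig(sessions_per_day=30.0, session_mean_minutes=0.5, seed=42)
person = generate_person(config)          # 7598 screens, 168 prompts, 79 responses
result = pipeline.run_person(
    person.events, person.prompts, person.responses, person.timeline
)
print(result.compliance.rounded())
# {'overall_pct': 47.0, 'response_day_pct': 50.6, 'mean_per_response_day': 3.04}
```

The simulated participant follows the standard design — 35 days of capture,
28 EMA days, hospitalization on days 29–32 — with a 5× injection of
risk-factor phrases on the day before hospitalization and compliance
decaying toward a floor of 0.1 from three days before the crisis. The
pipeline recovers both signatures from the raw streams:

```python
from screenome import (builtin_lexicon, normalize, filter_confidence,
                       remove_ema_screens, daily_counts, ratio_scores, top_k_words)

screens = [normalize(filter_confidence(e)) for e in person.events]
screens, removed = remove_ema_screens(screens, builtin_lexicon("ema_items"))  # 336 removed
series = ratio_scores(daily_counts(screens, builtin_lexicon("risk_factors"),
                                   person.timeline))
series.ratio.idxmax()     # 28  — the day before hospitalization
series.ratio.max()        # 0.126 of all risk-factor mentions on that one day
top_k_words(screens, builtin_lexicon("risk_factors"), 5)
# [('hopeless', 52), ('alone', 40), ('depression', 40), ('trap', 40), ('numb', 38)]
```

In `result.profile.frame`, `prompts_completed` is missing (not zero-filled)
from day 28 onward — the compliance collapse entering the crisis stays
visible in the joined table, while count-derived columns are observed
zeros.

The same stages are available from a shell:

```
screenome synth  --seed 42 -o data/
screenome ema    --prompts data/prompts.csv --responses data/responses.csv -o ema.csv
screenome score  --screens data/screens.jsonl --lexicon crisis.txt \
                 --timeline data/timeline.yaml -o scores.csv
screenome profile --screens data/screens.jsonl --prompts data/prompts.csv \
                  --responses data/responses.csv --timeline data/timeline.yaml \
                  -o profile.csv
```

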