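"""Dictionary scoring of normalized screens: phrase counts, daily/hourly
series, ratio scores, top words, app-category tags, and social-content
aggregation.

Scoring follows the word-count tradition: each lexicon (suicide-specific,
risk-factor, crisis, substances, ...) is counted independently, and daily
scores are displayed as ratios (day / total over the observation window)
rather than absolute mentions, so that persons with very different phone
use remain comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import Lexicon, ScreenEvent, StudyTimeline, ValidationError
from .text import NormalizedScreen

__all__ = [
    "DailyScoreSeries",
    "AppUsageSeries",
    "SocialContentSeries",
    "match_phrases",
    "daily_counts",
    "ratio_scores",
    "top_k_words",
    "hourly_counts",
    "tag_app_category",
    "daily_app_usage",
    "aggregate_social",
    "DEFAULT_APP_LEXICONS",
]

#: App-identification keyword defaults: screen text that betrays the app in
#: use.  "text" alone over-matches by design; swap in stricter lexicons via
#: the ``app_lexicons`` argument when needed.
DEFAULT_APP_LEXICONS: dict[str, Lexicon] = {
    "SMS": Lexicon("SMS", (("text", "message"), ("sms",), ("text",))),
    "Meta": Lexicon(
        "Meta",
        (
            ("write", "a", "comment"),
            ("what", "on", "your", "mind"),
            ("like",),
            ("facebook",),
            ("instagram",),
        ),
    ),
}


@dataclass
class DailyScoreSeries:
    """Per-day lexicon scores for one person.

    ``frame`` is indexed by study day (1..n_days) with columns ``raw_count``
    (nonnegative int) and ``ratio`` (day count / window total; all zero when
    nothing matched anywhere).
    """

    person_id: str
    lexicon_name: str
    frame: pd.DataFrame

    @property
    def raw(self) -> pd.Series:
        return self.frame["raw_count"]

    @property
    def ratio(self) -> pd.Series:
        return self.frame["ratio"]


@dataclass
class AppUsageSeries:
    """Per-day screen counts per app category (a screen may hit several)."""

    person_id: str
    frame: pd.DataFrame  # index: day, columns: categories


@dataclass
class SocialContentSeries:
    """Per-day sum of per-screen social probabilities (expected number of
    social screens that day)."""

    person_id: str
    values: pd.Series  # index: day


# ---------------------------------------------------------------------------
# Phrase matching
# ---------------------------------------------------------------------------


def match_phrases(screen: NormalizedScreen, lexicon: Lexicon) -> dict[str, int]:
    """Count non-overlapping lexicon phrase occurrences in a token stream.

    Scans left to right; at each position the longest matching entry wins
    and consumes its tokens, so a phrase and its sub-phrase never double
    count ("end it all" beats "end").  Returns ``{phrase-as-string: count}``
    for phrases with count > 0.
    """
    tokens = screen.tokens
    # index entries by first token, longest first (ties: lexicographic)
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for phrase in lexicon.entries:
        by_first.setdefault(phrase[0], []).append(phrase)
    for lst in by_first.values():
        lst.sort(key=lambda p: (-len(p), p))

    counts: dict[str, int] = {}
    i, n = 0, len(tokens)
    while i < n:
        candidates = by_first.get(tokens[i])
        if candidates:
            for phrase in candidates:
                k = len(phrase)
                if i + k <= n and tokens[i : i + k] == tuple(phrase):
                    key = " ".join(phrase)
                    counts[key] = counts.get(key, 0) + 1
                    i += k
                    break
            else:
                i += 1
        else:
            i += 1
    return counts


def _day_of(event: ScreenEvent, timeline: StudyTimeline) -> int:
    day = timeline.study_day(event.timestamp)
    if not (1 <= day <= timeline.n_days):
        raise ValidationError(
            f"screen at {event.timestamp.isoformat()} falls on study day {day}, "
            f"outside [1, {timeline.n_days}]"
        )
    return day


def daily_counts(
    screens: list[NormalizedScreen], lexicon: Lexicon, timeline: StudyTimeline
) -> DailyScoreSeries:
    """Total phrase matches per study day (raw counts; ratios all zero until
    :func:`ratio_scores` fills them).

    Suicide-related lexicons should be applied to EMA-filtered screens
    (see :func:`screenome.text.remove_ema_screens`).
    """
    days = pd.RangeIndex(1, timeline.n_days + 1, name="day")
    raw = pd.Series(0, index=days, dtype=int)
    for screen in screens:
        day = _day_of(screen.event, timeline)
        raw.loc[day] += sum(match_phrases(screen, lexicon).values())
    frame = pd.DataFrame({"raw_count": raw, "ratio": 0.0})
    return DailyScoreSeries(timeline.person_id, lexicon.name, frame)


def ratio_scores(series: DailyScoreSeries) -> DailyScoreSeries:
    """Convert raw daily counts to day/total ratios.

    Ratios sum to exactly 1 over the window, except the all-zero series,
    which stays all zero.
    """
    total = int(series.raw.sum())
    frame = series.frame.copy()
    frame["ratio"] = 0.0 if total == 0 else series.raw / total
    return DailyScoreSeries(series.person_id, series.lexicon_name, frame)


def top_k_words(
    screens: list[NormalizedScreen], lexicon: Lexicon, k: int
) -> list[tuple[str, int]]:
    """The ``k`` most-endorsed lexicon phrases over a screen stream.

    Sorted by descending total count, ties lexicographic; phrases that never
    matched are omitted (so fewer than ``k`` pairs may return).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    totals: dict[str, int] = {}
    for screen in screens:
        for phrase, c in match_phrases(screen, lexicon).items():
            totals[phrase] = totals.get(phrase, 0) + c
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def hourly_counts(screens: list[NormalizedScreen], lexicon: Lexicon) -> pd.Series:
    """Within-day trajectory: phrase matches per local hour (0-23).

    All screens must fall on one calendar day; the hourly sums add up to
    that day's raw count.
    """
    days = {s.event.local_date for s in screens}
    if len(days) > 1:
        raise ValidationError(f"screens span multiple days: {sorted(days)}")
    counts = pd.Series(0, index=pd.RangeIndex(0, 24, name="hour"), dtype=int)
    for screen in screens:
        counts.loc[screen.event.local_hour] += sum(match_phrases(screen, lexicon).values())
    return counts


# ---------------------------------------------------------------------------
# App category tagging and social-content aggregation
# ---------------------------------------------------------------------------


def tag_app_category(
    screen: NormalizedScreen,
    app_lexicons: dict[str, Lexicon] | None = None,
) -> set[str]:
    """Identify which app categories a screen's text betrays.

    A category applies when at least one of its keyword phrases occurs in
    the token stream; a screen may belong to several categories.
    """
    app_lexicons = DEFAULT_APP_LEXICONS if app_lexicons is None else app_lexicons
    tags: set[str] = set()
    for category, lexicon in app_lexicons.items():
        if match_phrases(screen, lexicon):
            tags.add(category)
    return tags


def daily_app_usage(
    screens: list[NormalizedScreen],
    timeline: StudyTimeline,
    app_lexicons: dict[str, Lexicon] | None = None,
) -> AppUsageSeries:
    """Per-day counts of screens tagged with each app category."""
    app_lexicons = DEFAULT_APP_LEXICONS if app_lexicons is None else app_lexicons
    days = pd.RangeIndex(1, timeline.n_days + 1, name="day")
    frame = pd.DataFrame(0, index=days, columns=list(app_lexicons), dtype=int)
    for screen in screens:
        day = _day_of(screen.event, timeline)
        for category in tag_app_category(screen, app_lexicons):
            frame.loc[day, category] += 1
    return AppUsageSeries(timeline.person_id, frame)


def aggregate_social(
    events: list[ScreenEvent], timeline: StudyTimeline
) -> SocialContentSeries:
    """Sum per-screen social-content probabilities by day.

    The day value is the expected number of social screens that day.  Events
    without a probability are skipped (missing, not zero).  If no event
    carries a probability the series is all-zero and a warning is issued.
    """
    days = pd.RangeIndex(1, timeline.n_days + 1, name="day")
    values = pd.Series(0.0, index=days)
    n_with = 0
    for ev in events:
        if ev.social_prob is None:
            continue
        values.loc[_day_of(ev, timeline)] += ev.social_prob
        n_with += 1
    if n_with == 0:
        warnings.warn(
            f"person {timeline.person_id!r}: no social probabilities present",
            stacklevel=2,
        )
    return SocialContentSeries(timeline.person_id, values)
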