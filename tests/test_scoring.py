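"""Lexicon scoring: phrase matching, daily/hourly aggregation, ratios,
top words, app tagging, social content."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screenome import (
    Lexicon,
    NormalizedScreen,
    aggregate_social,
    daily_app_usage,
    daily_counts,
    hourly_counts,
    match_phrases,
    normalize,
    ratio_scores,
    tag_app_category,
    top_k_words,
)
from screenome.io import ValidationError

from conftest import make_event


def screen_of(tokens, **kw) -> NormalizedScreen:
    return NormalizedScreen(event=make_event(**kw), tokens=tuple(tokens))


def oracle_match(tokens, entries) -> dict[str, int]:
    """Independent matcher: plain nested loops, longest-first at each
    position (ties lexicographic), non-overlapping left-to-right."""
    ranked = sorted(entries, key=lambda p: (-len(p), p))
    counts: dict[str, int] = {}
    i = 0
    while i < len(tokens):
        for phrase in ranked:
            if tuple(tokens[i : i + len(phrase)]) == tuple(phrase):
                key = " ".join(phrase)
                counts[key] = counts.get(key, 0) + 1
                i += len(phrase)
                break
        else:
            i += 1
    return counts


class TestMatchPhrases:
    def test_full_crisis_phrase_counts_once(self):
        lex = Lexicon("crisis", (("i", "just", "want", "this", "all", "to", "end"),))
        s = screen_of(["i", "just", "want", "this", "all", "to", "end"])
        assert match_phrases(s, lex) == {"i just want this all to end": 1}

    def test_empty_tokens_empty_counts(self):
        lex = Lexicon("l", (("end",),))
        assert match_phrases(screen_of([]), lex) == {}

    def test_longest_first_nonoverlapping_tiling(self):
        lex = Lexicon("l", (("end", "it", "all"), ("end",)))
        s = screen_of(["end", "it", "all", "end"])
        got = match_phrases(s, lex)
        assert got == {"end it all": 1, "end": 1}
        assert got == oracle_match(s.tokens, lex.entries)

    def test_total_equals_sum_of_matches(self):
        lex = Lexicon("l", (("pain",), ("alone",)))
        s = screen_of(["pain", "x", "pain", "alone"])
        assert sum(match_phrases(s, lex).values()) == 3

    @given(data=st.data())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        words = ["end", "it", "all", "pain", "alone", "x"]
        n_entries = data.draw(st.integers(1, 5))
        entries, seen = [], set()
        for _ in range(n_entries):
            phrase = tuple(
                data.draw(st.lists(st.sampled_from(words), min_size=1, max_size=3))
            )
            if phrase not in seen:
                seen.add(phrase)
                entries.append(phrase)
        lex = Lexicon("l", tuple(entries))
        tokens = data.draw(st.lists(st.sampled_from(words), max_size=12))
        s = screen_of(tokens)
        assert match_phrases(s, lex) == oracle_match(tokens, entries)

    def test_lexicon_entries_self_match(self):
        from screenome import builtin_lexicon

        for name in ("suicide", "risk_factors", "crisis", "substances", "ema_items"):
            lex = builtin_lexicon(name)
            for phrase in lex.entries:
                got = match_phrases(screen_of(phrase), lex)
                assert sum(got.values()) >= 1, phrase


class TestDailyCounts:
    def test_all_matches_on_one_day(self, timeline):
        lex = Lexicon("l", (("pain",),))
        screens = [screen_of(["pain", "pain"], day=7), screen_of(["x"], day=8)]
        series = daily_counts(screens, lex, timeline)
        assert series.raw.loc[7] == 2
        assert series.raw.drop(7).sum() == 0

    def test_order_invariance_within_day(self, timeline):
        lex = Lexicon("l", (("pain",), ("alone",)))
        screens = [screen_of(["pain"], day=3, second=0), screen_of(["alone"], day=3, second=5)]
        a = daily_counts(screens, lex, timeline).raw
        b = daily_counts(list(reversed(screens)), lex, timeline).raw
        assert (a == b).all()

    def test_additivity_over_day_partition(self, timeline):
        lex = Lexicon("l", (("pain",),))
        screens = [screen_of(["pain"], day=d) for d in (1, 1, 5, 9)]
        whole = daily_counts(screens, lex, timeline).raw
        parts = sum(
            daily_counts([s for s in screens if s.event.local_date == dte], lex, timeline).raw
            for dte in {s.event.local_date for s in screens}
        )
        assert (whole == parts).all()

    def test_screen_outside_window_raises(self, timeline):
        lex = Lexicon("l", (("pain",),))
        with pytest.raises(ValidationError, match="outside"):
            daily_counts([screen_of(["pain"], day=36)], lex, timeline)


class TestRatioScores:
    @pytest.mark.parametrize(
        "counts,expected",
        [([2, 3, 5], [0.2, 0.3, 0.5]), ([0, 0], [0.0, 0.0]), ([7], [1.0])],
    )
    def test_normalization_examples(self, counts, expected, timeline):
        import pandas as pd

        from screenome.scoring import DailyScoreSeries

        frame = pd.DataFrame(
            {"raw_count": counts, "ratio": 0.0},
            index=pd.RangeIndex(1, len(counts) + 1, name="day"),
        )
        series = ratio_scores(DailyScoreSeries("p1", "l", frame))
        assert np.allclose(series.ratio.to_numpy(), expected)

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_ratio_sum_is_exactly_zero_or_one(self, counts):
        import pandas as pd

        from screenome.scoring import DailyScoreSeries

        frame = pd.DataFrame(
            {"raw_count": counts, "ratio": 0.0},
            index=pd.RangeIndex(1, len(counts) + 1, name="day"),
        )
        total = ratio_scores(DailyScoreSeries("p1", "l", frame)).ratio.sum()
        assert abs(total - (0.0 if sum(counts) == 0 else 1.0)) < 1e-12


class TestTopKAndHourly:
    def test_top_k_orders_by_count_then_lexicographic(self):
        lex = Lexicon("l", (("pain",), ("alone",), ("numb",)))
        screens = [screen_of(["pain", "pain", "alone", "numb"])]
        assert top_k_words(screens, lex, 10) == [("pain", 2), ("alone", 1), ("numb", 1)]

    def test_top_1_unique_maximum(self):
        lex = Lexicon("l", (("pain",), ("alone",)))
        screens = [screen_of(["pain", "pain", "alone"])]
        assert top_k_words(screens, lex, 1) == [("pain", 2)]

    def test_all_zero_gives_empty_list(self):
        lex = Lexicon("l", (("pain",),))
        assert top_k_words([screen_of(["x"])], lex, 10) == []

    def test_hourly_counts_localized_and_sum_matches(self):
        lex = Lexicon("l", (("pain",),))
        screens = [
            screen_of(["pain"], hour=21, second=0),
            screen_of(["pain"], hour=21, second=300),
            screen_of(["x"], hour=9),
        ]
        counts = hourly_counts(screens, lex)
        assert counts.loc[21] == 2 and counts.sum() == 2

    def test_hourly_empty_day_all_zeros(self):
        lex = Lexicon("l", (("pain",),))
        assert hourly_counts([], lex).sum() == 0

    def test_hourly_mixed_days_raises(self):
        lex = Lexicon("l", (("pain",),))
        screens = [screen_of(["pain"], day=1), screen_of(["pain"], day=2)]
        with pytest.raises(ValidationError, match="multiple days"):
            hourly_counts(screens, lex)


class TestAppAndSocial:
    def _norm(self, text, **kw):
        return normalize(make_event(blocks=((text, 0.9),), **kw))

    def test_meta_keyword(self):
        assert tag_app_category(self._norm("Write a comment below")) == {"Meta"}

    def test_sms_keyword(self):
        assert tag_app_category(self._norm("new text message from mom")) == {"SMS"}

    def test_no_keywords_no_tags(self):
        assert tag_app_category(self._norm("weather today sunny")) == set()

    def test_screen_can_hit_both_categories(self):
        tags = tag_app_category(self._norm("sms me on facebook"))
        assert tags == {"SMS", "Meta"}

    def test_daily_app_usage_counts_screens(self, timeline):
        screens = [
            self._norm("open facebook now", day=2),
            self._norm("text message thread", day=2),
            self._norm("plain screen", day=2),
        ]
        series = daily_app_usage(screens, timeline)
        assert series.frame.loc[2, "Meta"] == 1
        assert series.frame.loc[2, "SMS"] == 1

    def test_aggregate_social_sums_by_day(self, timeline):
        events = [make_event(day=4, second=5 * i, social_prob=1.0) for i in range(3)]
        series = aggregate_social(events, timeline)
        assert series.values.loc[4] == pytest.approx(3.0)
        assert series.values.drop(4).sum() == 0

    def test_aggregate_social_linearity(self, timeline):
        events = [make_event(day=2, second=5 * i, social_prob=0.5) for i in range(10)]
        assert aggregate_social(events, timeline).values.loc[2] == pytest.approx(5.0)

    def test_no_probabilities_warns(self, timeline):
        events = [make_event(day=1)]
        with pytest.warns(UserWarning, match="no social"):
            series = aggregate_social(events, timeline)
        assert series.values.sum() == 0
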