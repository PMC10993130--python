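"""Synthetic-data generator: design conformance, determinism, and
parameter recovery."""

from __future__ import annotations

from dataclasses import replace
from datetime import timedelta

import numpy as np
import pytest

from screenome import (
    SyntheticConfig,
    align_to_event,
    builtin_lexicon,
    compliance,
    daily_counts,
    filter_confidence,
    generate_ema,
    generate_person,
    generate_text,
    generate_usage,
    mean_hourly_fraction,
    normalize,
    ratio_scores,
    summarize_item,
)
from screenome.io import ValidationError
from screenome.synth import person_a_like
from screenome.usage import hour_matrix


class TestUsageGeneration:
    def test_degenerate_intensity_puts_all_screens_in_that_hour(self, light_config):
        weights = tuple(1.0 if h == 20 else 0.0 for h in range(24))
        config = replace(light_config, hour_weights=weights, session_mean_minutes=0.1)
        slots = generate_usage(config, seed=5)
        for day_slots in slots.values():
            for sec in day_slots:
                assert sec // 3600 == 20

    def test_same_seed_same_stream(self, light_config):
        assert generate_usage(light_config, seed=9) == generate_usage(light_config, seed=9)

    def test_capacity_respected_and_gaps_are_5s(self, light_config):
        slots = generate_usage(light_config, seed=2)
        for day_slots in slots.values():
            assert all(b - a >= 5 for a, b in zip(day_slots, day_slots[1:]))
            per_hour = np.bincount([s // 3600 for s in day_slots], minlength=24)
            assert per_hour.max() <= 720

    def test_increasing_weights_give_nondecreasing_mean_fractions(self, light_config):
        # averaged over many seeds, the fitted hour profile follows the
        # nondecreasing intensity weights over the waking hours
        config = replace(light_config, sessions_per_day=12.0, session_mean_minutes=0.5)
        totals = np.zeros(24)
        for seed in range(30):
            person_slots = generate_usage(config, seed=seed)
            for day_slots in person_slots.values():
                totals += np.bincount([s // 3600 for s in day_slots], minlength=24)
        waking = totals[8:23]
        # allow small Monte-Carlo wiggle: each hour >= 90% of its predecessor
        assert all(b >= 0.9 * a for a, b in zip(waking, waking[1:]))


class TestTextGeneration:
    def test_zero_multipliers_zero_matches(self, light_config):
        config = replace(
            light_config,
            lexicon_rates={"risk_factors": 0.0},
            injection_multipliers={},
        )
        slots = generate_usage(config, seed=1)
        events, truth = generate_text(slots, config, seed=1)
        from screenome import match_phrases

        lex = builtin_lexicon("risk_factors")
        screens = [normalize(filter_confidence(e)) for e in events]
        assert sum(sum(match_phrases(s, lex).values()) for s in screens) == 0
        assert truth["risk_factors"] == {}

    def test_all_confidence_below_threshold_kills_all_tokens(self, light_config):
        config = replace(light_config, conf_below_frac=1.0)
        slots = generate_usage(config, seed=1)
        events, _ = generate_text(slots, config, seed=1)
        assert all(filter_confidence(e).blocks == () for e in events)

    def test_crisis_eve_injection_rate_ratio_near_multiplier(self, light_config):
        config = replace(light_config, sessions_per_day=12.0, conf_below_frac=0.0)
        eve = config.crisis_day - 1
        injected_eve = injected_other = screens_eve = screens_other = 0
        for seed in range(10):
            slots = generate_usage(config, seed=seed)
            _, truth = generate_text(slots, config, seed=seed)
            byday = truth["risk_factors"]
            injected_eve += byday.get(eve, 0)
            injected_other += sum(v for d, v in byday.items() if d != eve)
            screens_eve += len(slots[eve])
            screens_other += sum(len(s) for d, s in slots.items() if d != eve)
        # the *per-screen* injection rate carries the 5x multiplier; the
        # per-day count additionally reflects heavier pre-crisis phone use
        ratio = (injected_eve / screens_eve) / (injected_other / screens_other)
        assert 3.5 < ratio < 6.5

    def test_injected_day_attains_max_daily_ratio(self, light_config, timeline):
        config = replace(light_config, person_id="p1", sessions_per_day=8.0)
        person_slots = generate_usage(config, seed=11)
        events, _ = generate_text(person_slots, config, seed=11)
        screens = [normalize(filter_confidence(e)) for e in events]
        series = ratio_scores(daily_counts(screens, builtin_lexicon("risk_factors"), timeline))
        assert series.ratio.idxmax() == config.crisis_day - 1


class TestEmaGeneration:
    def test_28_days_gives_168_prompts_in_their_windows(self, light_config):
        prompts, responses, _ = generate_ema(light_config, seed=4)
        assert len(prompts) == 168
        for p in prompts:
            window_start = light_config.block_start_hour + 2 * (p.window_index - 1)
            offset = (
                p.issued_at.hour * 3600 + p.issued_at.minute * 60 + p.issued_at.second
            )
            assert window_start * 3600 <= offset < (window_start + 2) * 3600
        # completion inside the 30-minute validity
        by_key = {p.key: p for p in prompts}
        for r in responses:
            p = by_key[r.key]
            assert p.issued_at <= r.completed_at <= p.expires_at

    def test_full_compliance_when_probability_one(self, light_config):
        config = replace(
            light_config, compliance_base=1.0, compliance_floor=1.0, crisis_day=None
        )
        prompts, responses, _ = generate_ema(config, seed=4)
        s = compliance(prompts, responses)
        assert s.overall_pct == pytest.approx(100.0)

    def test_compliance_declines_into_crisis(self, light_config):
        p27 = light_config.compliance_prob(20)
        assert p27 == pytest.approx(light_config.compliance_base, abs=1e-3)
        floorish = light_config.compliance_prob(light_config.crisis_day - 1)
        assert floorish < 0.15

    def test_determinism(self, light_config):
        a = generate_ema(light_config, seed=8)
        b = generate_ema(light_config, seed=8)
        assert a[0] == b[0] and a[1] == b[1]


class TestGeneratePerson:
    def test_bundle_round_trips_through_io(self, tmp_path, light_config):
        from screenome import read_ema, read_screen_events, write_ema, write_screen_events

        person = generate_person(light_config, seed=6)
        write_screen_events(person.events, tmp_path / "s.jsonl")
        back = list(read_screen_events(tmp_path / "s.jsonl"))
        assert back == sorted(person.events, key=lambda e: (e.person_id, e.timestamp))
        write_ema(person.prompts, person.responses, tmp_path / "p.csv", tmp_path / "r.csv")
        bp, br = read_ema(tmp_path / "p.csv", tmp_path / "r.csv")
        assert bp == person.prompts and br == person.responses

    def test_identical_seed_identical_bundle(self, light_config):
        a = generate_person(light_config, seed=13)
        b = generate_person(light_config, seed=13)
        assert a.events == b.events
        assert a.prompts == b.prompts and a.responses == b.responses

    def test_person_a_like_pain_recovery(self):
        person = generate_person(person_a_like(seed=21))
        n, mean, sd = summarize_item(person.responses, "pain")
        assert n > 20
        # Monte-Carlo tolerance: 2 * sd / sqrt(n) around the generative mean
        assert abs(mean - 74.4) < 2 * 16.2 / np.sqrt(n) + 1.0

    def test_no_crisis_day_alignment_raises(self, light_config):
        import pandas as pd

        config = replace(light_config, crisis_day=None)
        person = generate_person(config, seed=2)
        series = pd.Series(0.0, index=pd.RangeIndex(1, config.n_days + 1))
        with pytest.raises(ValidationError):
            align_to_event(series, person.timeline)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(n_days=10, ema_days=11)
        with pytest.raises(ValidationError):
            SyntheticConfig(crisis_day=99)
        with pytest.raises(ValidationError):
            SyntheticConfig(conf_below_frac=1.5)
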