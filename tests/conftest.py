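"""Shared fixtures: tiny hand-built events and a light synthetic config.

The light config keeps the study design (35 days, 28 EMA days, crisis on
day 29) but dials usage down to a few short sessions per day so whole-suite
runtime stays small; tests that need volume generate it explicitly.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import pytest

from screenome import ScreenEvent, StudyTimeline, SyntheticConfig

TZ = timezone(timedelta(hours=-5))


@pytest.fixture
def tz():
    return TZ


@pytest.fixture
def timeline():
    return StudyTimeline(
        person_id="p1",
        study_start_day=date(2024, 1, 1),
        n_days=35,
        hospitalization_days=(29, 30, 31, 32),
    )


def make_event(
    day: int = 1,
    hour: int = 12,
    second: int = 0,
    blocks=(("hello world", 0.9),),
    person_id: str = "p1",
    social_prob: float | None = None,
) -> ScreenEvent:
    ts = datetime(2024, 1, 1, tzinfo=TZ) + timedelta(days=day - 1, hours=hour, seconds=second)
    return ScreenEvent(
        person_id=person_id, timestamp=ts, blocks=tuple(blocks), social_prob=social_prob
    )


@pytest.fixture
def event_factory():
    return make_event


@pytest.fixture
def light_config():
    return SyntheticConfig(
        sessions_per_day=6.0,
        session_mean_minutes=1.0,
        tokens_per_screen=10.0,
        seed=0,
    )
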