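"""Phone-use quantification from screenshot timestamps alone.

Each screenshot stands for one 5-second slot of phone use (the capture
cadence), so an hour holds at most 720 screenshots and the fraction of an
hour spent on the phone is ``count * 5 / 3600``; 360 screenshots mark 50%
use.  Days bin at local midnight, hours at local ``[h, h+1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import ScreenEvent, StudyTimeline, ValidationError

__all__ = [
    "UsageMatrix",
    "daily_screen_counts",
    "hour_matrix",
    "mean_hourly_fraction",
    "intensive_hours",
    "collection_hours",
    "SECONDS_PER_SLOT",
    "SLOTS_PER_HOUR",
]

SECONDS_PER_SLOT = 5
SLOTS_PER_HOUR = 3600 // SECONDS_PER_SLOT  # 720


@dataclass
class UsageMatrix:
    """Day x hour screenshot counts for one person.

    ``counts`` is indexed by study day with columns 0..23; ``fractions``
    divides by the 720-slot hourly capacity, giving the share of each hour
    spent on the phone.
    """

    person_id: str
    counts: pd.DataFrame

    @property
    def fractions(self) -> pd.DataFrame:
        return self.counts * SECONDS_PER_SLOT / 3600.0

    @property
    def daily_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def _collapse_slots(events: list[ScreenEvent]) -> list[ScreenEvent]:
    """Collapse duplicate events within one 5-second capture slot."""
    seen: set[tuple[str, int]] = set()
    out: list[ScreenEvent] = []
    dropped = 0
    for ev in events:
        slot = (ev.person_id, int(ev.timestamp.timestamp()) // SECONDS_PER_SLOT)
        if slot in seen:
            dropped += 1
            continue
        seen.add(slot)
        out.append(ev)
    if dropped:
        warnings.warn(f"collapsed {dropped} duplicate events within 5-s slots", stacklevel=3)
    return out


def daily_screen_counts(events: list[ScreenEvent], timeline: StudyTimeline) -> pd.Series:
    """Screenshots per study day; the sum over days equals the event count."""
    events = _collapse_slots(events)
    days = pd.RangeIndex(1, timeline.n_days + 1, name="day")
    counts = pd.Series(0, index=days, dtype=int)
    for ev in events:
        day = timeline.study_day(ev.timestamp)
        if not (1 <= day <= timeline.n_days):
            raise ValidationError(
                f"event at {ev.timestamp.isoformat()} on study day {day}, "
                f"outside [1, {timeline.n_days}]"
            )
        counts.loc[day] += 1
    return counts


def hour_matrix(events: list[ScreenEvent], timeline: StudyTimeline) -> UsageMatrix:
    """Day x hour screenshot counts; marginals match daily counts.

    Raises when any hour exceeds the 720-slot capacity (one screenshot per
    5-second slot).
    """
    events = _collapse_slots(events)
    days = pd.RangeIndex(1, timeline.n_days + 1, name="day")
    counts = pd.DataFrame(0, index=days, columns=pd.RangeIndex(0, 24, name="hour"), dtype=int)
    for ev in events:
        day = timeline.study_day(ev.timestamp)
        if not (1 <= day <= timeline.n_days):
            raise ValidationError(
                f"event at {ev.timestamp.isoformat()} on study day {day}, "
                f"outside [1, {timeline.n_days}]"
            )
        counts.loc[day, ev.local_hour] += 1
    if (counts > SLOTS_PER_HOUR).any().any():
        bad = counts.stack()
        bad = bad[bad > SLOTS_PER_HOUR]
        raise ValidationError(
            f"hourly capacity {SLOTS_PER_HOUR} exceeded at (day, hour) "
            f"{list(bad.index)}"
        )
    return UsageMatrix(timeline.person_id, counts)


def mean_hourly_fraction(matrix: UsageMatrix) -> pd.Series:
    """Average share of each hour spent on the phone, across all days.

    Zero-collection days inside the observation window count in the
    denominator.
    """
    if len(matrix.counts) < 1:
        raise ValidationError("usage matrix has no days")
    return matrix.fractions.mean(axis=0)


def intensive_hours(matrix: UsageMatrix) -> set[tuple[int, int]]:
    """(day, hour) cells with strictly more than 50% phone use."""
    frac = matrix.fractions
    stacked = frac.stack()
    return set(stacked[stacked > 0.5].index)


def collection_hours(day_count: int) -> float:
    """Hours of screenshot collection represented by a day's count."""
    if day_count < 0:
        raise ValidationError("count must be >= 0")
    return day_count * SECONDS_PER_SLOT / 3600.0
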