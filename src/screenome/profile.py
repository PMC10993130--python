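"""Hospitalization-aligned person-day risk profiles with loess trends.

The comparative analysis re-indexes every daily series so that relative day
0 is the first day of the person's hospitalization, then joins all passive
(lexicon scores, app use, social content, phone use) and active (EMA
composites, compliance, item means) series into one table per person-day.
Trend curves are loess: locally weighted linear regression with tricube
weights over the span-nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import StudyTimeline, ValidationError
from .scoring import AppUsageSeries, DailyScoreSeries, SocialContentSeries
from .usage import UsageMatrix, collection_hours

__all__ = [
    "RiskProfileTable",
    "align_to_event",
    "loess_trend",
    "build_profile",
]


@dataclass
class RiskProfileTable:
    """One row per (person, study day): every daily series side by side.

    ``relative_day`` is study_day minus the first hospitalization day, so
    the crisis sits at 0.  EMA-derived columns keep their missingness (a
    skipped day stays NaN); count-derived columns are zero-filled on days
    with collection.
    """

    frame: pd.DataFrame  # index: (person_id, study_day)


def align_to_event(series: pd.Series, timeline: StudyTimeline) -> pd.Series:
    """Re-index a study-day series by day relative to first hospitalization.

    Order-preserving; values untouched.  Raises when the timeline has no
    hospitalization recorded.
    """
    event_day = timeline.first_hospitalization_day  # raises if none
    out = series.copy()
    out.index = pd.Index(series.index - event_day, name="relative_day")
    return out


def loess_trend(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    span: float = 0.75,
) -> np.ndarray:
    """Loess smooth: local linear fit with tricube weights, evaluated at x.

    For each target point the ``ceil(span * n)`` nearest neighbors (by
    |x - x0|) get tricube weights ``(1 - (d/dmax)^3)^3`` and a weighted
    straight line is fit; the fitted value at the target is returned.  No
    robustness iterations.  Reproduces constants and straight lines exactly.

    Parameters
    ----------
    x, y : 1-d arrays of equal length; NaNs in y are dropped for fitting
        but fitted values are returned at every x.
    span : fraction of points in each local neighborhood, in (0, 1].
    """
    if not (0.0 < span <= 1.0):
        raise ValidationError(f"span {span} outside (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(x)
    xs, ys = x[ok], y[ok]
    n = len(xs)
    if n < 4:
        raise ValidationError(f"loess needs >= 4 nonmissing points, got {n}")
    k = max(2, int(np.ceil(span * n)))

    fitted = np.empty(len(x))
    for i, x0 in enumerate(x):
        d = np.abs(xs - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = ys[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        xi, yi = xs[idx], ys[idx]
        # weighted straight-line fit via normal equations
        sw = w.sum()
        xm = (w * xi).sum() / sw
        ym = (w * yi).sum() / sw
        sxx = (w * (xi - xm) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xm * xm):
            fitted[i] = ym
        else:
            beta = (w * (xi - xm) * (yi - ym)).sum() / sxx
            fitted[i] = ym + beta * (x0 - xm)
    return fitted


def build_profile(
    timeline: StudyTimeline,
    *,
    score_series: list[DailyScoreSeries] | None = None,
    app_usage: AppUsageSeries | None = None,
    social: SocialContentSeries | None = None,
    usage_matrix: UsageMatrix | None = None,
    ema_daily: pd.DataFrame | None = None,
    compliance_daily: pd.Series | None = None,
) -> RiskProfileTable:
    """Join every per-day series into one hospitalization-aligned table.

    All inputs must belong to ``timeline``'s person and index study days.
    ``ema_daily`` columns (composites, item means, flags) keep NaN on days
    without responses; score/usage columns are filled with 0 (no matches /
    no screens is an observed zero).  ``relative_day`` is present only when
    a hospitalization is recorded.
    """
    days = pd.RangeIndex(1, timeline.n_days + 1, name="study_day")
    frame = pd.DataFrame(index=days)
    frame["person_id"] = timeline.person_id

    if timeline.hospitalization_days:
        frame["relative_day"] = days - timeline.first_hospitalization_day
        frame["hospitalized"] = [
            int(d in set(timeline.hospitalization_days)) for d in days
        ]

    def _check_person(pid: str, what: str) -> None:
        if pid != timeline.person_id:
            raise ValidationError(
                f"{what} belongs to {pid!r}, timeline to {timeline.person_id!r}"
            )

    for s in score_series or []:
        _check_person(s.person_id, f"score series {s.lexicon_name!r}")
        frame[f"{s.lexicon_name}_count"] = s.raw.reindex(days, fill_value=0)
        frame[f"{s.lexicon_name}_ratio"] = s.ratio.reindex(days, fill_value=0.0)

    if app_usage is not None:
        _check_person(app_usage.person_id, "app usage")
        for col in app_usage.frame.columns:
            frame[f"app_{col}_screens"] = app_usage.frame[col].reindex(days, fill_value=0)

    if social is not None:
        _check_person(social.person_id, "social content")
        frame["social_prob_sum"] = social.values.reindex(days, fill_value=0.0)

    if usage_matrix is not None:
        _check_person(usage_matrix.person_id, "usage matrix")
        totals = usage_matrix.daily_totals.reindex(days, fill_value=0)
        frame["screens"] = totals
        frame["collection_hours"] = [collection_hours(int(c)) for c in totals]

    if ema_daily is not None:
        for col in ema_daily.columns:
            frame[col] = ema_daily[col].reindex(days)

    if compliance_daily is not None:
        frame["prompts_completed"] = compliance_daily.reindex(days)

    frame = frame.reset_index().set_index(["person_id", "study_day"])
    return RiskProfileTable(frame)
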