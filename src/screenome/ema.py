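"""EMA-derived metrics: compliance, composite suicide scores, risk-factor
series, and person-specific high-score flags.

The active-assessment protocol is signal-contingent: 6 prompts/day in 2-hour
windows over a participant-selected 12-hour block, each answerable for 30
minutes.  Compliance is completed-within-protocol prompts over prompts
received.  Momentary suicidal ideation (4 Likert items), planning (3) and
desire (2) are summed into composites; "high" observations are those at or
above the person-specific empirical 90th percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EmaPrompt, EmaResponse, ValidationError

__all__ = [
    "ItemRegistry",
    "DEFAULT_ITEM_REGISTRY",
    "ComplianceSummary",
    "CompositeScores",
    "HighFlagSeries",
    "compliance",
    "composite_scores",
    "high_flags",
    "daily_binary_series",
    "summarize_item",
    "daily_ema_frame",
    "round1",
]


def round1(x: float) -> float:
    """Round half away from zero to one decimal (reporting convention)."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ItemRegistry:
    """Names, types, and composite membership of the EMA items.

    ``types`` maps item name -> "likert" | "binary" | "pain";
    ``ideation``/``planning``/``desire`` list the constituent item names of
    each composite (4, 3, and 2 Likert items respectively).
    """

    types: dict[str, str]
    ideation: tuple[str, ...]
    planning: tuple[str, ...]
    desire: tuple[str, ...]

    def __post_init__(self) -> None:
        for group, expect in (
            (self.ideation, 4),
            (self.planning, 3),
            (self.desire, 2),
        ):
            if len(group) != expect:
                raise ValidationError(
                    f"composite {group} has {len(group)} items, expected {expect}"
                )
            for name in group:
                if name not in self.types:
                    raise ValidationError(f"unknown item name in registry: {name!r}")
                if self.types[name] != "likert":
                    raise ValidationError(f"composite item {name!r} must be Likert")


#: The study's item set: momentary ideation (passive + active), planning
#: since last prompt, momentary desire, plus risk-factor and sleep items.
DEFAULT_ITEM_REGISTRY = ItemRegistry(
    types={
        "life_not_worth_living": "likert",
        "more_reasons_to_die": "likert",
        "want_to_die": "likert",
        "think_about_taking_life": "likert",
        "considered_method": "likert",
        "identified_acquire_method": "likert",
        "made_preparations": "likert",
        "urge_attempt": "likert",
        "desire_kill_self": "likert",
        "thwarted_belongingness": "likert",
        "perceived_burdensomeness": "likert",
        "negative_affect": "likert",
        "positive_affect": "likert",
        "nssi_urge": "likert",
        "alcohol_urge": "likert",
        "drug_urge": "likert",
        "sleep_quality": "likert",
        "interpersonal_conflict": "binary",
        "nssi_behavior": "binary",
        "alcohol_use": "binary",
        "nightmares": "binary",
        "pain": "pain",
    },
    ideation=(
        "life_not_worth_living",
        "more_reasons_to_die",
        "want_to_die",
        "think_about_taking_life",
    ),
    planning=("considered_method", "identified_acquire_method", "made_preparations"),
    desire=("urge_attempt", "desire_kill_self"),
)


@dataclass(frozen=True)
class ComplianceSummary:
    """Prompt-completion statistics for one person.

    ``overall_pct`` divides by all prompts received; ``response_day_pct``
    divides by 6 x the number of days with at least one completed response,
    quantifying completion on days the person engaged at all.
    """

    person_id: str
    prompts_received: int
    prompts_completed: int
    response_days: int
    overall_pct: float
    response_day_pct: float | None
    mean_per_response_day: float | None

    def rounded(self) -> dict[str, float | None]:
        """Reporting view: percentages to one decimal, mean to two."""
        return {
            "overall_pct": round1(self.overall_pct),
            "response_day_pct": (
                None if self.response_day_pct is None else round1(self.response_day_pct)
            ),
            "mean_per_response_day": (
                None
                if self.mean_per_response_day is None
                else round(self.mean_per_response_day, 2)
            ),
        }


def compliance(
    prompts: list[EmaPrompt], responses: list[EmaResponse]
) -> ComplianceSummary:
    """Compute compliance from joined prompts and within-expiry responses.

    A *response day* is a study day with >= 1 completed response; response-
    day metrics are None when there are none.
    """
    if not prompts:
        raise ValidationError("no prompts received")
    person_ids = {p.person_id for p in prompts}
    if len(person_ids) != 1:
        raise ValidationError(f"prompts span multiple persons: {sorted(person_ids)}")
    person_id = prompts[0].person_id

    received = len(prompts)
    keys = {p.key for p in prompts}
    completed_keys = {r.key for r in responses}
    if not completed_keys <= keys:
        raise ValidationError(f"responses without prompts: {sorted(completed_keys - keys)}")
    completed = len(completed_keys)
    if completed > received:
        raise ValidationError("more completed than received prompts")
    response_days = len({r.study_day for r in responses})

    overall = 100.0 * completed / received
    if response_days == 0:
        return ComplianceSummary(person_id, received, completed, 0, overall, None, None)
    return ComplianceSummary(
        person_id=person_id,
        prompts_received=received,
        prompts_completed=completed,
        response_days=response_days,
        overall_pct=overall,
        response_day_pct=100.0 * completed / (6 * response_days),
        mean_per_response_day=completed / response_days,
    )


@dataclass(frozen=True)
class CompositeScores:
    """Summed composites for one response; None when any constituent item is
    missing (listwise per composite, no prorating)."""

    ideation: int | None  # 4..20
    planning: int | None  # 3..15
    desire: int | None  # 2..10


def composite_scores(
    response: EmaResponse, registry: ItemRegistry = DEFAULT_ITEM_REGISTRY
) -> CompositeScores:
    """Sum the ideation/planning/desire items of one completed response."""

    def total(names: tuple[str, ...]) -> int | None:
        vals = [response.items.get(n) for n in names]
        if any(v is None for v in vals):
            return None
        return int(sum(vals))  # type: ignore[arg-type]

    return CompositeScores(
        ideation=total(registry.ideation),
        planning=total(registry.planning),
        desire=total(registry.desire),
    )


@dataclass(frozen=True)
class HighFlagSeries:
    """Values with person-specific high flags.

    ``threshold`` is the empirical 90th percentile (linear interpolation
    between order statistics); ``flags[i]`` is True iff
    ``values[i] >= threshold`` ("at or above").
    """

    variable: str
    values: pd.Series
    threshold: float
    flags: pd.Series


def high_flags(values: pd.Series, variable: str = "") -> HighFlagSeries:
    """Flag observations at or above the person-specific 90th percentile."""
    clean = values.dropna()
    if len(clean) < 2:
        raise ValidationError("high_flags needs >= 2 nonmissing values")
    threshold = float(np.quantile(clean.to_numpy(dtype=float), 0.9, method="linear"))
    flags = values >= threshold
    flags[values.isna()] = False
    return HighFlagSeries(variable=variable, values=values, threshold=threshold, flags=flags)


def daily_binary_series(
    responses: list[EmaResponse],
    item: str,
    registry: ItemRegistry = DEFAULT_ITEM_REGISTRY,
) -> pd.Series:
    """Collapse a binary item to a day series: any endorsement -> 1.

    Days with >= 1 completed response and no endorsement are 0; days with no
    response are absent from the index (missing, not zero).
    """
    if registry.types.get(item) != "binary":
        raise ValidationError(f"item {item!r} is not registered as binary")
    by_day: dict[int, int] = {}
    for r in responses:
        v = r.items.get(item)
        if v is None:
            continue
        by_day[r.study_day] = max(by_day.get(r.study_day, 0), int(v))
    return pd.Series(by_day, dtype=int).sort_index().rename(item)


def daily_ema_frame(
    responses: list[EmaResponse],
    registry: ItemRegistry = DEFAULT_ITEM_REGISTRY,
) -> pd.DataFrame:
    """Per-day EMA summary: mean composites, mean pain, prompts completed.

    Indexed by study day; days without any completed response are simply
    absent (missing, never zero-filled — compliance gaps must stay
    visible).  Composite means average over responses whose composite is
    computable.
    """
    rows: dict[int, dict[str, list[float]]] = {}
    for r in responses:
        comp = composite_scores(r, registry)
        bucket = rows.setdefault(r.study_day, {"i": [], "p": [], "d": [], "pain": [], "n": []})
        bucket["n"].append(1.0)
        if comp.ideation is not None:
            bucket["i"].append(comp.ideation)
        if comp.planning is not None:
            bucket["p"].append(comp.planning)
        if comp.desire is not None:
            bucket["d"].append(comp.desire)
        pain = r.items.get("pain")
        if pain is not None:
            bucket["pain"].append(float(pain))

    def _mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else np.nan

    frame = pd.DataFrame(
        {
            "ideation_mean": {d: _mean(b["i"]) for d, b in rows.items()},
            "planning_mean": {d: _mean(b["p"]) for d, b in rows.items()},
            "desire_mean": {d: _mean(b["d"]) for d, b in rows.items()},
            "pain_mean": {d: _mean(b["pain"]) for d, b in rows.items()},
            "n_completed": {d: len(b["n"]) for d, b in rows.items()},
        }
    )
    frame.index.name = "day"
    return frame.sort_index()


def summarize_item(
    responses: list[EmaResponse], item: str
) -> tuple[int, float, float | None]:
    """n, mean, and sample SD (n-1 denominator) of a numeric item.

    SD is None for a single observation.
    """
    vals = [r.items[item] for r in responses if item in r.items]
    if not vals:
        raise ValidationError(f"no responses carry item {item!r}")
    arr = np.asarray(vals, dtype=float)
    n = len(arr)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else None
    return n, mean, sd
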