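"""End-to-end orchestration: raw events + EMA records -> risk profile table.

Glue over the stage modules, used by the command-line interface and by the
end-to-end tests.  The stage order is the one the analysis runs in:
confidence filtering, normalization, EMA-screen removal, lexicon scoring,
app/social aggregation, usage matrices, EMA metrics, profile join.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ema import ComplianceSummary, compliance, daily_ema_frame
from .io import EmaPrompt, EmaResponse, Lexicon, ScreenEvent, StudyTimeline
from .profile import RiskProfileTable, build_profile
from .scoring import (
    aggregate_social,
    daily_app_usage,
    daily_counts,
    ratio_scores,
)
from .synth import builtin_lexicon
from .text import (
    OCR_CONFIDENCE_THRESHOLD,
    filter_confidence,
    normalize,
    remove_ema_screens,
)
from .usage import hour_matrix

__all__ = ["PipelineResult", "run_person"]


@dataclass
class PipelineResult:
    """Everything the pipeline derives for one person."""

    profile: RiskProfileTable
    compliance: ComplianceSummary | None
    n_ema_screens_removed: int


def run_person(
    events: list[ScreenEvent],
    prompts: list[EmaPrompt],
    responses: list[EmaResponse],
    timeline: StudyTimeline,
    lexicons: list[Lexicon] | None = None,
    ema_item_phrases: Lexicon | None = None,
    ocr_threshold: float = OCR_CONFIDENCE_THRESHOLD,
) -> PipelineResult:
    """Run the full per-person analysis and join the daily series.

    ``lexicons`` defaults to the built-in fixture dictionaries (suicide,
    risk_factors, crisis, substances); ``ema_item_phrases`` defaults to the
    built-in EMA item wordings used to strip survey screens before scoring.
    """
    if lexicons is None:
        lexicons = [
            builtin_lexicon(n) for n in ("suicide", "risk_factors", "crisis", "substances")
        ]
    if ema_item_phrases is None:
        ema_item_phrases = builtin_lexicon("ema_items")

    filtered = [filter_confidence(e, ocr_threshold) for e in events]
    normalized = [normalize(e) for e in filtered]
    scored_screens, n_removed = remove_ema_screens(normalized, ema_item_phrases)

    score_series = [
        ratio_scores(daily_counts(scored_screens, lex, timeline)) for lex in lexicons
    ]
    app_usage = daily_app_usage(normalized, timeline)
    social = aggregate_social(events, timeline)
    matrix = hour_matrix(events, timeline)

    summary = compliance(prompts, responses) if prompts else None
    ema_daily = daily_ema_frame(responses) if responses else None
    compliance_daily = ema_daily["n_completed"] if ema_daily is not None else None
    if ema_daily is not None:
        ema_daily = ema_daily.drop(columns=["n_completed"])

    profile = build_profile(
        timeline,
        score_series=score_series,
        app_usage=app_usage,
        social=social,
        usage_matrix=matrix,
        ema_daily=ema_daily,
        compliance_daily=compliance_daily,
    )
    return PipelineResult(profile=profile, compliance=summary, n_ema_screens_removed=n_removed)
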