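"""Synthetic person generator: screen-text streams, EMA records, timelines.

The study's raw data are protected, so every pipeline stage is exercised on
simulated participants that reproduce the design and the qualitative
structure of the real data: screenshots every 5 seconds during usage
sessions, phone use increasing across the day and rising toward a crisis,
6 EMA prompts/day in 2-hour windows over a 12-hour block for 28 days,
compliance declining as the crisis approaches, and elevated rates of
specific lexicon phrases (e.g. "pain", "alone") on the day(s) before
hospitalization.  Ground-truth parameters are returned alongside the data
so recovery tests can compare estimate against truth.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta, timezone

import numpy as np

from .io import EmaPrompt, EmaResponse, Lexicon, ScreenEvent, StudyTimeline, ValidationError
from .text import default_normalizer

__all__ = [
    "SyntheticConfig",
    "SyntheticPerson",
    "builtin_lexicon",
    "BUILTIN_LEXICON_PHRASES",
    "generate_usage",
    "generate_text",
    "generate_ema",
    "generate_person",
    "person_a_like",
]

# ---------------------------------------------------------------------------
# Built-in fixture lexicons
# ---------------------------------------------------------------------------

#: Small fixture lexicons: the phrases publicly associated with each
#: dictionary plus clearly generic placeholders.  These are test fixtures,
#: not reconstructions of any proprietary word list.
BUILTIN_LEXICON_PHRASES: dict[str, tuple[str, ...]] = {
    "suicide": ("kill myself", "end it all", "suicide", "take my life"),
    "risk_factors": (
        "trapped",
        "crying",
        "pain",
        "alone",
        "guilty",
        "anxiety",
        "depression",
        "numb",
        "hopeless",
        "burden",
    ),
    "crisis": (
        "hurt myself",
        "i just want this all to end",
        "hate my life",
        "hopeless",
        "drown",
        "rope",
        "give up",
        "cant go on",
    ),
    "substances": ("weed", "marijuana", "alcohol", "drug", "painkiller", "pills"),
    # Rendered EMA item wordings, used to strip survey screens before
    # suicide-lexicon scoring.
    "ema_items": (
        "life is not worth living for me",
        "there are more reasons to die than to live",
        "i want to die",
        "i think about taking my life",
        "considered a specific suicide method",
        "identified how to acquire your suicide method",
        "made other preparations for your death",
        "how strong is your urge to make a suicide attempt",
        "how intense is your desire to kill yourself",
    ),
}


def builtin_lexicon(name: str) -> Lexicon:
    """A built-in fixture lexicon, normalized with the default normalizer."""
    try:
        phrases = BUILTIN_LEXICON_PHRASES[name]
    except KeyError:
        raise ValidationError(
            f"no built-in lexicon {name!r}; have {sorted(BUILTIN_LEXICON_PHRASES)}"
        ) from None
    entries: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for raw in phrases:
        phrase = tuple(default_normalizer(raw))
        if phrase and phrase not in seen:
            seen.add(phrase)
            entries.append(phrase)
    return Lexicon(name=name, entries=tuple(entries))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_hour_weights() -> tuple[float, ...]:
    # little use overnight, then intensity increasing across the waking day
    w = [0.05] * 24
    for h in range(7, 24):
        w[h] = float(h - 6)
    return tuple(w)


def _default_lexicon_rates() -> dict[str, float]:
    return {"suicide": 0.01, "risk_factors": 0.05, "crisis": 0.02, "substances": 0.03}


def _default_binary_probs() -> dict[str, float]:
    return {
        "interpersonal_conflict": 0.25,
        "nssi_behavior": 0.05,
        "alcohol_use": 0.10,
        "nightmares": 0.30,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of one simulated participant.

    Defaults mirror the study design (35 days of capture, 28 EMA days with
    6 prompts/day in 2-hour windows over a 12-hour block) and a mid-study
    crisis with hospitalization on day 29.  Usage defaults target roughly
    4 hours of capture per day; pain defaults are the published per-person
    summary (mean 74.4, SD 16.2).
    """

    person_id: str = "synthetic-01"
    study_start: date = date(2024, 1, 1)
    utc_offset_hours: int = -5
    n_days: int = 35
    ema_days: int = 28
    crisis_day: int | None = 29
    hospitalization_length: int = 4

    # -- usage profile
    hour_weights: tuple[float, ...] = field(default_factory=_default_hour_weights)
    sessions_per_day: float = 40.0
    session_mean_minutes: float = 6.0
    usage_crisis_multiplier: float = 1.5  # gradual rise over the final pre-crisis week

    # -- screen text
    vocab_size: int = 500
    tokens_per_screen: float = 10.0
    lexicon_rates: dict[str, float] = field(default_factory=_default_lexicon_rates)
    injection_multipliers: dict[str, dict[int, float]] | None = None
    conf_below_frac: float = 0.10  # share of OCR blocks under the 0.70 cutoff
    render_ema_screens: bool = True
    social_screen_frac: float = 0.20

    # -- compliance
    compliance_base: float = 0.60
    compliance_floor: float = 0.10
    compliance_onset_before_crisis: int = 3
    compliance_steepness: float = 4.0

    # -- EMA items
    block_start_hour: int = 9  # 12-hour block 09:00-21:00
    severity_base: float = 1.5
    severity_peak: float = 4.0
    severity_ramp_days: int = 14
    pain_mean: float = 74.4
    pain_sd: float = 16.2
    binary_probs: dict[str, float] = field(default_factory=_default_binary_probs)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.ema_days < 1 or self.ema_days > self.n_days:
            raise ValidationError("need 1 <= ema_days <= n_days")
        if self.crisis_day is not None and not (1 <= self.crisis_day <= self.n_days):
            raise ValidationError(f"crisis_day {self.crisis_day} outside [1, {self.n_days}]")
        if len(self.hour_weights) != 24 or any(w < 0 for w in self.hour_weights):
            raise ValidationError("hour_weights must be 24 nonnegative values")
        for p in (
            self.conf_below_frac,
            self.compliance_base,
            self.compliance_floor,
            self.social_screen_frac,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.injection_multipliers is not None:
            for lex, byday in self.injection_multipliers.items():
                if any(m < 0 for m in byday.values()):
                    raise ValidationError(f"negative multiplier for lexicon {lex!r}")

    @property
    def tz(self) -> timezone:
        return timezone(timedelta(hours=self.utc_offset_hours))

    def multipliers(self) -> dict[str, dict[int, float]]:
        """Injection multipliers; by default a 5x spike of risk-factor and
        substance phrases on crisis eve, matching the signature the analysis
        is meant to recover."""
        if self.injection_multipliers is not None:
            return self.injection_multipliers
        if self.crisis_day is None or self.crisis_day < 2:
            return {}
        eve = self.crisis_day - 1
        return {"risk_factors": {eve: 5.0}, "substances": {eve: 5.0}}

    def timeline(self) -> StudyTimeline:
        hosp: tuple[int, ...] = ()
        if self.crisis_day is not None:
            last = min(self.n_days, self.crisis_day + self.hospitalization_length - 1)
            hosp = tuple(range(self.crisis_day, last + 1))
        return StudyTimeline(
            person_id=self.person_id,
            study_start_day=self.study_start,
            n_days=self.n_days,
            hospitalization_days=hosp,
        )

    def compliance_prob(self, day: int) -> float:
        """Per-prompt answer probability: logistic ramp from the baseline to
        the floor, starting ``compliance_onset_before_crisis`` days before
        the crisis."""
        p0, fl = self.compliance_base, self.compliance_floor
        if self.crisis_day is None:
            return p0
        onset = self.crisis_day - self.compliance_onset_before_crisis
        z = self.compliance_steepness * (day - onset + 0.5)
        if z > 500:
            return fl
        return fl + (p0 - fl) / (1.0 + math.exp(z))


def person_a_like(seed: int = 0) -> SyntheticConfig:
    """Preset echoing the first case's published summary: hospitalization
    beginning day 29 of 35, pain mean 74.4 (SD 16.2), heavier phone use."""
    return SyntheticConfig(
        person_id="person-a-like",
        crisis_day=29,
        hospitalization_length=4,
        sessions_per_day=50.0,
        session_mean_minutes=7.0,
        pain_mean=74.4,
        pain_sd=16.2,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

_SECONDS_PER_DAY = 86400
_SLOT = 5


def _rng(config: SyntheticConfig, seed: int | None, stream: int) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), stream]))


def _usage_day_multiplier(config: SyntheticConfig, day: int) -> float:
    """Phone use ramps up over the week before the crisis."""
    if config.crisis_day is None or config.usage_crisis_multiplier == 1.0:
        return 1.0
    lead = config.crisis_day - day
    if lead < 0 or lead > 7:
        return 1.0
    return 1.0 + (config.usage_crisis_multiplier - 1.0) * (1.0 - lead / 7.0)


def generate_usage(
    config: SyntheticConfig, seed: int | None = None
) -> dict[int, list[int]]:
    """Simulate usage sessions; returns day -> sorted 5-s slot start seconds.

    Session start hours follow the hour-of-day intensity weights, session
    lengths are exponential, and a screenshot occupies every 5-second slot
    within a session.  Overlapping sessions merge (one screenshot per slot),
    so the 720/hour capacity holds by construction.
    """
    rng = _rng(config, seed, stream=1)
    weights = np.asarray(config.hour_weights, dtype=float)
    weights = weights / weights.sum()
    mean_slots = max(1.0, config.session_mean_minutes * 60.0 / _SLOT)

    out: dict[int, list[int]] = {}
    for day in range(1, config.n_days + 1):
        lam = config.sessions_per_day * _usage_day_multiplier(config, day)
        n_sessions = rng.poisson(lam)
        slots: set[int] = set()
        for _ in range(n_sessions):
            hour = int(rng.choice(24, p=weights))
            start_sec = hour * 3600 + int(rng.integers(0, 3600))
            start_slot = start_sec // _SLOT
            length = max(1, int(math.ceil(rng.exponential(mean_slots))))
            end_slot = min(start_slot + length, _SECONDS_PER_DAY // _SLOT)
            slots.update(range(start_slot, end_slot))
        out[day] = [s * _SLOT for s in sorted(slots)]
    return out


def _build_vocab(config: SyntheticConfig, reserved: set[str]) -> list[str]:
    """Deterministic background vocabulary of pseudo-words, avoiding any
    token that appears in a configured lexicon (no accidental matches)."""
    rng = np.random.default_rng(np.random.SeedSequence([987654321, config.vocab_size]))
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < config.vocab_size:
        length = int(rng.integers(3, 9))
        word = "".join(rng.choice(letters, size=length))
        lemmas = default_normalizer(word)
        lemma = lemmas[0] if lemmas else ""
        if not lemma or lemma in reserved or word in seen:
            continue
        seen.add(word)
        vocab.append(word)
    return vocab


def generate_text(
    day_slots: dict[int, list[int]],
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[list[ScreenEvent], dict[str, dict[int, int]]]:
    """Attach OCR-like text blocks to a usage stream.

    Each screen gets background pseudo-words; for each configured lexicon,
    phrases are injected as contiguous token runs at uniform positions with
    per-screen Poisson rate ``r0 * m_d`` on day ``d``.  Block confidences
    come from a two-component mixture so a configurable share falls below
    the 0.70 OCR cutoff.  Returns the events plus ground-truth injected
    counts per lexicon per day.
    """
    rng = _rng(config, seed, stream=2)
    lexicons = {
        name: builtin_lexicon(name) for name in config.lexicon_rates
    }
    reserved = {tok for lex in lexicons.values() for p in lex.entries for tok in p}
    reserved |= {tok for p in builtin_lexicon("ema_items").entries for tok in p}
    vocab = _build_vocab(config, reserved)
    multipliers = config.multipliers()
    timeline = config.timeline()
    tz = config.tz

    events: list[ScreenEvent] = []
    truth: dict[str, dict[int, int]] = {name: {} for name in lexicons}

    def _confidence() -> float:
        if rng.random() < config.conf_below_frac:
            return float(rng.uniform(0.30, 0.699))
        return float(rng.uniform(0.70, 1.0))

    for day, slot_seconds in sorted(day_slots.items()):
        midnight = datetime.combine(timeline.date_of(day), time(0), tz)
        for sec in slot_seconds:
            n_bg = max(1, int(rng.poisson(config.tokens_per_screen)))
            tokens = list(rng.choice(len(vocab), size=n_bg))
            tokens = [vocab[i] for i in tokens]
            for name, r0 in config.lexicon_rates.items():
                m = multipliers.get(name, {}).get(day, 1.0)
                k = int(rng.poisson(r0 * m))
                if k == 0:
                    continue
                truth[name][day] = truth[name].get(day, 0) + k
                entries = lexicons[name].entries
                for _ in range(k):
                    phrase = entries[int(rng.integers(0, len(entries)))]
                    pos = int(rng.integers(0, len(tokens) + 1))
                    tokens[pos:pos] = list(phrase)
            blocks = [(" ".join(tokens), _confidence())]
            if rng.random() < 0.25:
                extra = [vocab[i] for i in rng.choice(len(vocab), size=3)]
                blocks.append((" ".join(extra), _confidence()))
            social = None
            if rng.random() < config.social_screen_frac:
                social = float(np.clip(rng.beta(5, 2), 0.0, 1.0))
            elif rng.random() < 0.5:
                social = float(np.clip(rng.beta(2, 8), 0.0, 1.0))
            events.append(
                ScreenEvent(
                    person_id=config.person_id,
                    timestamp=midnight + timedelta(seconds=sec),
                    blocks=tuple(blocks),
                    social_prob=social,
                )
            )
    return events, truth


def _ema_prompt_screens(
    prompts: list[EmaPrompt], config: SyntheticConfig, rng: np.random.Generator
) -> list[ScreenEvent]:
    """Screens showing the survey itself (to exercise EMA-screen removal)."""
    wordings = BUILTIN_LEXICON_PHRASES["ema_items"]
    out: list[ScreenEvent] = []
    for p in prompts:
        for j in range(2):
            wording = wordings[int(rng.integers(0, len(wordings)))]
            out.append(
                ScreenEvent(
                    person_id=config.person_id,
                    timestamp=p.issued_at + timedelta(seconds=_SLOT * j),
                    blocks=((wording, float(rng.uniform(0.75, 1.0))),),
                    social_prob=None,
                )
            )
    return out


def generate_ema(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[list[EmaPrompt], list[EmaResponse], dict]:
    """Simulate the signal-contingent EMA protocol.

    Exactly ``6 * ema_days`` prompts, each uniform within its 2-hour window
    of the 12-hour block; each answered with the day's compliance
    probability, with completion uniform within the 30-minute validity.
    Item values come from a latent severity trajectory rising toward the
    crisis (ordinal items), the configured pain distribution, and Bernoulli
    binaries.  Returns (prompts, responses, ground truth).
    """
    rng = _rng(config, seed, stream=3)
    tz = config.tz
    timeline = config.timeline()
    prompts: list[EmaPrompt] = []
    responses: list[EmaResponse] = []
    p_by_day: dict[int, float] = {}

    for day in range(1, config.ema_days + 1):
        p_day = config.compliance_prob(day)
        p_by_day[day] = p_day
        midnight = datetime.combine(timeline.date_of(day), time(0), tz)
        # latent severity for the day
        if config.crisis_day is None:
            sev = config.severity_base
        else:
            lead = max(0, config.crisis_day - day)
            frac = max(0.0, 1.0 - lead / config.severity_ramp_days)
            sev = config.severity_base + (config.severity_peak - config.severity_base) * frac
        for w in range(1, 7):
            window_start = (config.block_start_hour + 2 * (w - 1)) * 3600
            issued = midnight + timedelta(
                seconds=window_start + int(rng.integers(0, 7200))
            )
            prompt = EmaPrompt(
                person_id=config.person_id, study_day=day, window_index=w, issued_at=issued
            )
            prompts.append(prompt)
            if rng.random() >= p_day:
                continue
            completed = issued + timedelta(seconds=int(rng.integers(0, 1800)))
            latent = sev + rng.normal(0.0, 0.7)
            items: dict[str, float] = {}

            def likert(center: float) -> int:
                return int(np.clip(round(center + rng.normal(0.0, 0.8)), 1, 5))

            for name in (
                "life_not_worth_living",
                "more_reasons_to_die",
                "want_to_die",
                "think_about_taking_life",
                "urge_attempt",
                "desire_kill_self",
                "thwarted_belongingness",
                "perceived_burdensomeness",
                "negative_affect",
                "nssi_urge",
                "alcohol_urge",
                "drug_urge",
            ):
                items[name] = likert(latent)
            for name in ("considered_method", "identified_acquire_method", "made_preparations"):
                items[name] = likert(max(1.0, latent - 0.8))
            items["positive_affect"] = likert(6.0 - latent)
            items["pain"] = float(
                int(np.clip(round(rng.normal(config.pain_mean, config.pain_sd)), 0, 100))
            )
            for name, pb in config.binary_probs.items():
                items[name] = int(rng.random() < pb)
            if w == 1:  # morning prompt carries the sleep items
                items["sleep_quality"] = likert(6.0 - latent)
            else:
                items.pop("nightmares", None)
            responses.append(
                EmaResponse(
                    person_id=config.person_id,
                    study_day=day,
                    window_index=w,
                    completed_at=completed,
                    items=items,
                )
            )
    truth = {
        "compliance_prob_by_day": p_by_day,
        "pain_mean": config.pain_mean,
        "pain_sd": config.pain_sd,
        "severity_base": config.severity_base,
        "severity_peak": config.severity_peak,
    }
    return prompts, responses, truth


@dataclass
class SyntheticPerson:
    """A complete simulated participant plus generator ground truth."""

    config: SyntheticConfig
    timeline: StudyTimeline
    events: list[ScreenEvent]
    prompts: list[EmaPrompt]
    responses: list[EmaResponse]
    truth: dict


def generate_person(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> SyntheticPerson:
    """Generate one internally consistent participant bundle.

    Usage, text, and EMA use independent random streams derived from one
    seed, so the bundle is reproducible end to end.  The returned truth dict
    records injected lexicon counts by day and the EMA generative
    parameters, the targets of the recovery tests.
    """
    config = SyntheticConfig() if config is None else config
    if seed is not None:
        config = replace(config, seed=seed)
    day_slots = generate_usage(config)
    events, injected = generate_text(day_slots, config)
    prompts, responses, ema_truth = generate_ema(config)
    if config.render_ema_screens:
        rng = _rng(config, None, stream=4)
        extra = _ema_prompt_screens([p for p in prompts], config, rng)
        events = sorted(events + extra, key=lambda e: e.timestamp)
    truth = {"injected": injected, **ema_truth, "seed": config.seed}
    return SyntheticPerson(
        config=config,
        timeline=config.timeline(),
        events=events,
        prompts=prompts,
        responses=responses,
        truth=truth,
    )
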