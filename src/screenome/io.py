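"""Domain types and readers/writers for screen-event, EMA, and lexicon data.

The pipeline's unit of passive observation is the *screen event*: one
screenshot captured during phone use (nominally every 5 seconds), reduced to
the text blocks an OCR engine extracted from it, each with a confidence in
[0, 1].  Active data are ecological momentary assessment (EMA) prompts and
their item-level responses.  Lexicons are phrase lists used for dictionary
scoring of the screen text.

All timestamps are timezone-aware with one fixed UTC offset per person;
calendar-day and hour binning happens in that local offset.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ScreenEvent",
    "StudyTimeline",
    "EmaPrompt",
    "EmaResponse",
    "Lexicon",
    "read_screen_events",
    "write_screen_events",
    "read_ema",
    "write_ema",
    "load_lexicon",
    "read_timeline",
    "write_timeline",
    "PROMPT_VALIDITY",
    "PROMPT_REMINDER",
    "PROMPTS_PER_DAY",
]

#: How long a prompt stays answerable after delivery.
PROMPT_VALIDITY = timedelta(minutes=30)
#: When the single reminder fires.
PROMPT_REMINDER = timedelta(minutes=15)
#: Signal-contingent design: six 2-hour windows across a 12-hour block.
PROMPTS_PER_DAY = 6


class ValidationError(ValueError):
    """A record violated a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenEvent:
    """One captured screen: OCR text blocks with confidences.

    Parameters
    ----------
    person_id
        Opaque participant identifier.
    timestamp
        Timezone-aware capture instant; the offset defines local time.
    blocks
        Ordered ``(text, confidence)`` pairs in reading order.
    social_prob
        Optional probability (from an external screen classifier) that the
        screen shows social-app content.
    """

    person_id: str
    timestamp: datetime
    blocks: tuple[tuple[str, float], ...]
    social_prob: float | None = None

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ValidationError("timestamp must be timezone-aware")
        for text, conf in self.blocks:
            if not (0.0 <= conf <= 1.0):
                raise ValidationError(
                    f"block confidence {conf!r} outside [0, 1] (text={text!r})"
                )
        if self.social_prob is not None and not (0.0 <= self.social_prob <= 1.0):
            raise ValidationError(f"social_prob {self.social_prob!r} outside [0, 1]")

    @property
    def local_date(self) -> date:
        """Calendar day in the participant's recorded offset."""
        return self.timestamp.date()

    @property
    def local_hour(self) -> int:
        return self.timestamp.hour


@dataclass(frozen=True)
class StudyTimeline:
    """Per-person study window with optional hospitalization span.

    ``study_start_day`` is the calendar date of study day 1; study days run
    1..n_days.  ``hospitalization_days`` are study-day integers and must be
    contiguous when present (an inpatient stay).
    """

    person_id: str
    study_start_day: date
    n_days: int
    hospitalization_days: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValidationError("n_days must be positive")
        days = self.hospitalization_days
        if days:
            if any(d < 1 or d > self.n_days for d in days):
                raise ValidationError(
                    f"hospitalization_days {days} outside [1, {self.n_days}]"
                )
            if list(days) != list(range(days[0], days[-1] + 1)):
                raise ValidationError(f"hospitalization_days {days} not contiguous")

    def study_day(self, ts: datetime | date) -> int:
        """Map an instant (or date) to its 1-based study day."""
        d = ts.date() if isinstance(ts, datetime) else ts
        return (d - self.study_start_day).days + 1

    def date_of(self, study_day: int) -> date:
        return self.study_start_day + timedelta(days=study_day - 1)

    @property
    def first_hospitalization_day(self) -> int:
        if not self.hospitalization_days:
            raise ValidationError(
                f"person {self.person_id!r} has no hospitalization recorded"
            )
        return self.hospitalization_days[0]


@dataclass(frozen=True)
class EmaPrompt:
    """A scheduled EMA prompt; answerable for 30 minutes after delivery."""

    person_id: str
    study_day: int
    window_index: int  # 1..6
    issued_at: datetime

    def __post_init__(self) -> None:
        if not (1 <= self.window_index <= PROMPTS_PER_DAY):
            raise ValidationError(f"window_index {self.window_index} outside [1, 6]")
        if self.study_day < 1:
            raise ValidationError("study_day must be >= 1")

    @property
    def expires_at(self) -> datetime:
        return self.issued_at + PROMPT_VALIDITY

    @property
    def reminder_at(self) -> datetime:
        return self.issued_at + PROMPT_REMINDER

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.person_id, self.study_day, self.window_index)


#: Item types accepted in responses, with their valid ranges.
_LIKERT = frozenset(range(1, 6))


@dataclass(frozen=True)
class EmaResponse:
    """A completed prompt: item-name -> value map.

    Likert items take values 1..5, binary items 0/1, pain 0..100.  Items
    absent from the map are missing (the respondent skipped them).
    """

    person_id: str
    study_day: int
    window_index: int
    completed_at: datetime
    items: Mapping[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.person_id, self.study_day, self.window_index)

    def validate_against(self, registry: Mapping[str, str]) -> None:
        """Check each answered item against its registered type."""
        for name, value in self.items.items():
            kind = registry.get(name)
            if kind is None:
                continue
            if kind == "likert" and value not in _LIKERT:
                raise ValidationError(f"Likert item {name!r} value {value!r} not in 1..5")
            if kind == "binary" and value not in (0, 1):
                raise ValidationError(f"binary item {name!r} value {value!r} not in {{0,1}}")
            if kind == "pain" and not (0 <= value <= 100):
                raise ValidationError(f"pain item {name!r} value {value!r} outside [0,100]")


@dataclass(frozen=True)
class Lexicon:
    """A named set of normalized phrases; each phrase is a token tuple.

    Entries are stored already normalized (lowercased, lemmatized, alphabetic
    tokens only) so that matching against normalized screen text is exact
    regardless of which normalizer produced them — provided text and lexicon
    share one normalizer.
    """

    name: str
    entries: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"lexicon {self.name!r} has no entries")
        seen = set()
        for phrase in self.entries:
            if not phrase:
                raise ValidationError(f"lexicon {self.name!r} contains an empty phrase")
            for tok in phrase:
                if not tok or not tok.isalpha() or tok != tok.lower():
                    raise ValidationError(
                        f"lexicon {self.name!r} token {tok!r} is not a lowercase "
                        "alphabetic word"
                    )
            if phrase in seen:
                raise ValidationError(f"lexicon {self.name!r} duplicates {phrase!r}")
            seen.add(phrase)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, phrase: tuple[str, ...]) -> bool:
        return phrase in set(self.entries)


# ---------------------------------------------------------------------------
# Screen event JSON-lines I/O
# ---------------------------------------------------------------------------


def read_screen_events(path: str | Path) -> Iterator[ScreenEvent]:
    """Read screen events from a JSON-lines file, per person in time order.

    One record per line::

        {"person_id": ..., "ts": ISO-8601 with offset,
         "blocks": [{"text": ..., "conf": ...}, ...], "social_prob": optional}

    Events are yielded sorted by ``(person_id, timestamp)``.  Malformed lines
    raise :class:`ValidationError` naming the line number.
    """
    events: list[ScreenEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                ev = ScreenEvent(
                    person_id=str(rec["person_id"]),
                    timestamp=datetime.fromisoformat(rec["ts"]),
                    blocks=tuple((str(b["text"]), float(b["conf"])) for b in rec["blocks"]),
                    social_prob=(
                        float(rec["social_prob"]) if rec.get("social_prob") is not None else None
                    ),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            except (KeyError, ValueError, TypeError) as exc:
                raise ValidationError(f"{path}:{lineno}: malformed record ({exc})") from exc
            events.append(ev)
    events.sort(key=lambda e: (e.person_id, e.timestamp))
    yield from events


def write_screen_events(events: Iterable[ScreenEvent], path: str | Path) -> int:
    """Write events as JSON-lines; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            rec: dict = {
                "person_id": ev.person_id,
                "ts": ev.timestamp.isoformat(),
                "blocks": [{"text": t, "conf": c} for t, c in ev.blocks],
            }
            if ev.social_prob is not None:
                rec["social_prob"] = ev.social_prob
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# EMA CSV I/O
# ---------------------------------------------------------------------------

_PROMPT_COLS = ["person_id", "study_day", "window_index", "issued_at"]
_RESPONSE_META = ["person_id", "study_day", "window_index", "completed_at"]


def read_ema(
    prompt_path: str | Path,
    response_path: str | Path | None = None,
    item_registry: Mapping[str, str] | None = None,
) -> tuple[list[EmaPrompt], list[EmaResponse]]:
    """Read prompts and (optionally) responses; join and validate.

    Every response must join to exactly one prompt on
    ``(person_id, study_day, window_index)``; an orphan raises.  Responses
    completed after the prompt's 30-minute expiry are dropped with a warning
    — they do not count toward compliance.
    """
    prompts: list[EmaPrompt] = []
    with open(prompt_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_PROMPT_COLS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"{prompt_path}: missing prompt columns {sorted(missing)}")
        for rec in reader:
            prompts.append(
                EmaPrompt(
                    person_id=rec["person_id"],
                    study_day=int(rec["study_day"]),
                    window_index=int(rec["window_index"]),
                    issued_at=datetime.fromisoformat(rec["issued_at"]),
                )
            )
    by_key = {p.key: p for p in prompts}
    if len(by_key) != len(prompts):
        raise ValidationError(f"{prompt_path}: duplicate prompt keys")

    responses: list[EmaResponse] = []
    if response_path is not None:
        with open(response_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            fields = reader.fieldnames or []
            missing = set(_RESPONSE_META) - set(fields)
            if missing:
                raise ValidationError(
                    f"{response_path}: missing response columns {sorted(missing)}"
                )
            item_cols = [c for c in fields if c not in _RESPONSE_META]
            for rec in reader:
                key = (rec["person_id"], int(rec["study_day"]), int(rec["window_index"]))
                prompt = by_key.get(key)
                if prompt is None:
                    raise ValidationError(f"{response_path}: orphan response for prompt {key}")
                completed_at = datetime.fromisoformat(rec["completed_at"])
                items = {
                    c: float(rec[c]) for c in item_cols if rec.get(c) not in (None, "")
                }
                resp = EmaResponse(
                    person_id=key[0],
                    study_day=key[1],
                    window_index=key[2],
                    completed_at=completed_at,
                    items=items,
                )
                if item_registry is not None:
                    resp.validate_against(item_registry)
                if completed_at > prompt.expires_at:
                    warnings.warn(
                        f"response to prompt {key} completed after expiry; excluded",
                        stacklevel=2,
                    )
                    continue
                responses.append(resp)
    return prompts, responses


def write_ema(
    prompts: Sequence[EmaPrompt],
    responses: Sequence[EmaResponse],
    prompt_path: str | Path,
    response_path: str | Path,
    item_names: Sequence[str] | None = None,
) -> None:
    """Write prompts/responses to the documented CSV schemas."""
    with open(prompt_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PROMPT_COLS)
        for p in prompts:
            writer.writerow([p.person_id, p.study_day, p.window_index, p.issued_at.isoformat()])

    if item_names is None:
        names: list[str] = []
        for r in responses:
            for k in r.items:
                if k not in names:
                    names.append(k)
        item_names = names
    with open(response_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RESPONSE_META + list(item_names))
        for r in responses:
            row: list = [r.person_id, r.study_day, r.window_index, r.completed_at.isoformat()]
            for name in item_names:
                v = r.items.get(name)
                row.append("" if v is None else (int(v) if float(v).is_integer() else v))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Timeline YAML
# ---------------------------------------------------------------------------


def write_timeline(timeline: StudyTimeline, path: str | Path) -> None:
    import yaml

    doc = {
        "person_id": timeline.person_id,
        "study_start_day": timeline.study_start_day.isoformat(),
        "n_days": timeline.n_days,
        "hospitalization_days": list(timeline.hospitalization_days),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_timeline(path: str | Path) -> StudyTimeline:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return StudyTimeline(
        person_id=str(doc["person_id"]),
        study_start_day=date.fromisoformat(doc["study_start_day"]),
        n_days=int(doc["n_days"]),
        hospitalization_days=tuple(int(d) for d in doc.get("hospitalization_days") or ()),
    )


# ---------------------------------------------------------------------------
# Lexicon files
# ---------------------------------------------------------------------------


def load_lexicon(
    path: str | Path,
    normalizer: Callable[[str], list[str]],
    name: str | None = None,
) -> Lexicon:
    """Load a one-phrase-per-line lexicon, normalizing with ``normalizer``.

    Blank lines and ``#`` comments are ignored.  Phrases identical after
    normalization collapse to one entry.  An empty result raises.
    """
    path = Path(path)
    entries: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            phrase = tuple(normalizer(line))
            if phrase and phrase not in seen:
                seen.add(phrase)
                entries.append(phrase)
    if not entries:
        raise ValidationError(f"{path}: lexicon empty after cleaning")
    return Lexicon(name=name or path.stem, entries=tuple(entries))
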