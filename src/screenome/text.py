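"""Screen-text normalization: confidence filtering, lemmatization, EMA-screen
removal, and day-level sampling.

OCR is a pluggable boundary: everything here consumes ``(text, confidence)``
pairs, so any OCR engine — or the synthetic generator — can feed the
pipeline.  Normalization follows the standard screen-text recipe: case
reduction, removal of punctuation and numbers, lemmatization.  The
lemmatizer is a compact rule system (irregular-form table plus suffix rules
for plurals, -ing and -ed forms); it is deterministic and shared between
screen text and lexicons so phrase matching stays consistent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import Lexicon, ScreenEvent, ValidationError

__all__ = [
    "NormalizedScreen",
    "RuleLemmatizer",
    "default_normalizer",
    "tokenize",
    "filter_confidence",
    "normalize",
    "remove_ema_screens",
    "dedup_consecutive",
    "sample_day_screens",
    "OCR_CONFIDENCE_THRESHOLD",
]

#: Default OCR confidence cutoff: blocks with confidence < 0.70 are dropped.
OCR_CONFIDENCE_THRESHOLD = 0.70

_WORD_RE = re.compile(r"[a-z]+")

# Irregular and closed-class forms the suffix rules would mangle.
_IRREGULAR = {
    "is": "be", "am": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "doing": "do", "done": "do",
    "goes": "go", "went": "go", "gone": "go", "going": "go",
    "dying": "die", "died": "die", "dies": "die", "lying": "lie", "lied": "lie",
    "felt": "feel", "feeling": "feel", "thought": "think", "thinking": "think",
    "said": "say", "says": "say", "saying": "say",
    "made": "make", "making": "make", "taking": "take", "took": "take", "taken": "take",
    "left": "leave", "leaving": "leave", "got": "get", "getting": "get",
    "lives": "life", "this": "this", "his": "his", "us": "us", "its": "its",
    "as": "as",
    "myself": "myself", "yourself": "yourself", "themselves": "themselves",
    "anxious": "anxious", "hopeless": "hopeless", "worthless": "worthless",
    "always": "always", "perhaps": "perhaps", "news": "news", "yes": "yes",
    "sms": "sms",
}

_VOWELS = set("aeiou")

_DOUBLED = re.compile(r"([b-df-hj-np-tv-z])\1$")


def _lemma_once(word: str) -> str:
    w = _IRREGULAR.get(word)
    if w is not None:
        return w
    n = len(word)
    # -ing: crying -> cry, running -> run, hoping -> hope
    if n > 5 and word.endswith("ing"):
        stem = word[:-3]
        if _DOUBLED.search(stem) and len(stem) > 3:
            return stem[:-1]
        if len(stem) == 3 and stem[-1] not in _VOWELS and stem[-2] in _VOWELS:
            return stem + "e"
        return stem
    # -ied/-ies: cried -> cry, cries -> cry
    if n > 4 and (word.endswith("ied") or word.endswith("ies")):
        return word[:-3] + "y"
    # -ed: trapped -> trap, wanted -> want
    if n > 4 and word.endswith("ed"):
        stem = word[:-2]
        if _DOUBLED.search(stem) and len(stem) > 3:
            return stem[:-1]
        return stem
    # -es after sibilants: wishes -> wish, boxes -> box
    if n > 3 and word.endswith("es") and (
        word[-3] in "sxz" or word[-4:-2] in ("ch", "sh")
    ):
        return word[:-2]
    # plain plural -s (not -ss)
    if n > 3 and word.endswith("s") and not word.endswith("ss"):
        return word[:-1]
    return word


@lru_cache(maxsize=65536)
def _lemma(word: str) -> str:
    """Dictionary base form of a single lowercase alphabetic word.

    Rules are applied to a fixed point, so every lemma is its own lemma —
    this makes the full normalization idempotent, which phrase matching
    relies on (text and lexicon meet in the same normalized space).
    """
    prev, cur = None, word
    while cur != prev:
        prev, cur = cur, _lemma_once(cur)
    return cur


class RuleLemmatizer:
    """Callable normalizer: free text -> lowercase alphabetic lemmas.

    Splits on every non-alphabetic character (so punctuation and digits
    vanish), lowercases, then applies the lemma rules per token.
    """

    def __call__(self, text: str) -> list[str]:
        return [_lemma(tok) for tok in _WORD_RE.findall(text.lower())]


#: Module-level normalizer shared by screen text and lexicon loading.
default_normalizer = RuleLemmatizer()


def tokenize(text: str) -> list[str]:
    """Lowercase alphabetic tokens without lemmatization."""
    return _WORD_RE.findall(text.lower())


@dataclass(frozen=True)
class NormalizedScreen:
    """A screen event reduced to its normalized token stream."""

    event: ScreenEvent
    tokens: tuple[str, ...]

    @property
    def person_id(self) -> str:
        return self.event.person_id


def filter_confidence(
    event: ScreenEvent, threshold: float = OCR_CONFIDENCE_THRESHOLD
) -> ScreenEvent:
    """Drop OCR blocks whose confidence is strictly below ``threshold``.

    The boundary is retained: a block at exactly the threshold survives.
    Idempotent and monotone in the threshold.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    kept = tuple((t, c) for t, c in event.blocks if c >= threshold)
    if len(kept) == len(event.blocks):
        return event
    return ScreenEvent(event.person_id, event.timestamp, kept, event.social_prob)


def normalize(event: ScreenEvent, normalizer=default_normalizer) -> NormalizedScreen:
    """Normalize an event's blocks into one token stream.

    Blocks are concatenated in reading order; tokens are lowercased,
    stripped of punctuation and digits, and lemmatized.  Idempotent on its
    own output (lemmas are fixed points of the lemma rules by construction
    of the irregulars table; residual non-fixed-points re-lemmatize to
    themselves after one pass through ``normalize``).
    """
    tokens: list[str] = []
    for text, _conf in event.blocks:
        tokens.extend(normalizer(text))
    return NormalizedScreen(event=event, tokens=tuple(tokens))


def _contains_phrase(tokens: tuple[str, ...], phrase: tuple[str, ...]) -> bool:
    k = len(phrase)
    if k == 0 or k > len(tokens):
        return False
    return any(tokens[i : i + k] == phrase for i in range(len(tokens) - k + 1))


def remove_ema_screens(
    screens: list[NormalizedScreen], ema_item_phrases: Lexicon
) -> tuple[list[NormalizedScreen], int]:
    """Drop screens showing the EMA survey itself.

    A screen is removed when its token stream contains at least one full EMA
    item phrase (e.g. the rendered wording "I want to die"); this prevents
    the survey's own wording from inflating suicide-lexicon scores.  Returns
    ``(kept_screens, n_removed)`` with relative order preserved.
    """
    if len(ema_item_phrases) == 0:  # Lexicon forbids this, but guard anyway
        raise ValidationError("EMA item phrase lexicon is empty")
    kept: list[NormalizedScreen] = []
    removed = 0
    for screen in screens:
        if any(_contains_phrase(screen.tokens, p) for p in ema_item_phrases.entries):
            removed += 1
        else:
            kept.append(screen)
    return kept, removed


def dedup_consecutive(screens: list[NormalizedScreen]) -> list[NormalizedScreen]:
    """Collapse runs of consecutive screens with identical token streams.

    Off by default in the pipeline: a static screen legitimately re-counts
    every 5 s of continued exposure.  Offered for sensitivity analyses.
    """
    out: list[NormalizedScreen] = []
    for s in screens:
        if out and out[-1].tokens == s.tokens:
            continue
        out.append(s)
    return out


def sample_day_screens(
    screens: list[ScreenEvent], n: int, seed: int | np.random.Generator
) -> list[ScreenEvent]:
    """Uniform sample without replacement of ``min(n, len(screens))`` events.

    Used for qualitative review of a single day (e.g. 1000 screenshots from
    the day before hospitalization).  Reproducible given the seed; output
    preserves chronological order.
    """
    if n < 1:
        raise ValidationError("sample size must be >= 1")
    if len(screens) <= n:
        return list(screens)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(screens), size=n, replace=False)
    return [screens[i] for i in sorted(idx)]
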