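"""Keyword scanning and negation filtering for PI mentions in clinical notes.

Nursing notes frequently mention pressure injuries in the negative ("no
bedsore observed") or as a structured dismissal ("bedsore: none"); counting
those as PI evidence would flood the keyword labeling route with false
positives.  The scanner here finds lexicon phrases with word-boundary
matching and marks a mention negated when a trigger word occurs within a
fixed token window before it in the same sentence, or a dismissal pattern
surrounds it — a deliberately simple trigger-window scheme in the NegEx
tradition, not a contextual model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Optional, Sequence

from .ehr_model import ClinicalNote

DEFAULT_PHRASES = (
    "pressure ulcer",
    "pressure injury",
    "pressure sore",
    "decubitus ulcer",
    "decubitus",
    "bedsore",
    "bed sore",
)

DEFAULT_NEGATION_TRIGGERS = (
    "no",
    "not",
    "without",
    "denies",
    "negative for",
    "free of",
    "ruled out",
    "no evidence of",
)

#: Structured dismissals: the phrase immediately followed by ": none" etc.
DEFAULT_DISMISSAL_SUFFIXES = (": none", ": neg", ": negative", ": 0", ": denied")

_SENTENCE_BOUNDARY = re.compile(r"[.!?\n]")
_TOKEN = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class KeywordLexicon:
    """Case-insensitive PI phrase list plus negation configuration."""

    phrases: Sequence[str] = DEFAULT_PHRASES
    negation_triggers: Sequence[str] = DEFAULT_NEGATION_TRIGGERS
    dismissal_suffixes: Sequence[str] = DEFAULT_DISMISSAL_SUFFIXES
    window_tokens: int = 5

    def __post_init__(self):
        if not self.phrases:
            raise ValueError("lexicon requires at least one phrase")
        if self.window_tokens < 1:
            raise ValueError("window_tokens must be >= 1")

    @classmethod
    def from_config(cls, cfg: dict) -> "KeywordLexicon":
        return cls(
            phrases=tuple(cfg.get("phrases", DEFAULT_PHRASES)),
            negation_triggers=tuple(cfg.get("negation_triggers", DEFAULT_NEGATION_TRIGGERS)),
            dismissal_suffixes=tuple(cfg.get("dismissal_suffixes", DEFAULT_DISMISSAL_SUFFIXES)),
            window_tokens=int(cfg.get("window_tokens", 5)),
        )

    def phrase_pattern(self) -> re.Pattern:
        # longest phrase first so "pressure ulcer" wins over any shorter
        # overlapping phrase; \b guards stop "decubitus" matching inside a
        # longer word
        parts = sorted(self.phrases, key=len, reverse=True)
        alts = "|".join(re.escape(p).replace(r"\ ", r"\s+") for p in parts)
        return re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)


@dataclass(frozen=True)
class PIMention:
    note_id: str
    stay_id: str
    start: int
    end: int
    phrase: str
    negated: bool
    ts: Optional[datetime]
    date_only: bool = False


def _tokens_between(text: str, start: int, end: int) -> int:
    return len(_TOKEN.findall(text[start:end].lower()))


def is_negated(text: str, start: int, end: int, lex: KeywordLexicon) -> bool:
    """Trigger-window negation test for the phrase at ``text[start:end]``.

    True when a negation trigger ends within ``window_tokens`` tokens before
    the phrase in the same sentence (sentence boundaries: ``. ! ?`` or
    newline), or when a dismissal suffix immediately follows the phrase.
    """
    lowered = text.lower()
    # structured dismissal, e.g. "bedsore: none"
    tail = lowered[end:]
    tail_norm = re.sub(r"\s+", " ", tail)
    for suffix in lex.dismissal_suffixes:
        if tail_norm.startswith(suffix.lower()):
            return True

    sent_start = 0
    for m in _SENTENCE_BOUNDARY.finditer(lowered, 0, start):
        sent_start = m.end()
    sentence_prefix = lowered[sent_start:start]

    for trigger in lex.negation_triggers:
        t = trigger.lower()
        for m in re.finditer(rf"\b{re.escape(t)}\b", sentence_prefix):
            gap_tokens = _tokens_between(sentence_prefix, m.end(), len(sentence_prefix))
            if gap_tokens <= lex.window_tokens - 1:
                # trigger counts as one of the window_tokens tokens
                return True
    return False


def scan_note(note: ClinicalNote, lex: KeywordLexicon) -> list[PIMention]:
    """All non-overlapping PI phrase mentions in a note, flagged for negation.

    Matches are found longest-phrase-first and left to right; empty note
    text yields an empty list.  The same note and lexicon always produce an
    identical mention list.
    """
    text = note.text or ""
    if not text:
        return []
    mentions = []
    for m in lex.phrase_pattern().finditer(text):
        mentions.append(PIMention(
            note_id=note.note_id,
            stay_id=note.stay_id,
            start=m.start(),
            end=m.end(),
            phrase=m.group(0),
            negated=is_negated(text, m.start(), m.end(), lex),
            ts=note.ts,
            date_only=note.date_only,
        ))
    return mentions


def scan_notes(notes: Iterable[ClinicalNote], lex: KeywordLexicon) -> list[PIMention]:
    out: list[PIMention] = []
    for note in notes:
        out.extend(scan_note(note, lex))
    return out


def earliest_positive_mention(
    notes: Iterable[ClinicalNote],
    lex: KeywordLexicon,
    min_hours: float,
    admit_ts: datetime,
    include_date_only: bool = True,
) -> Optional[tuple[datetime, PIMention]]:
    """Earliest non-negated mention strictly later than ``min_hours`` after
    admission, or None.

    Date-only notes carry a 00:00 timestamp, which under-approximates the
    true charting time: using it for the strict ``>`` comparison can only
    miss borderline mentions, never invent one.  Definitions that require
    time-stamped notes pass ``include_date_only=False``.
    """
    best: Optional[tuple[datetime, PIMention]] = None
    for note in notes:
        if note.ts is None:
            continue
        if note.date_only and not include_date_only:
            continue
        hours = (note.ts - admit_ts).total_seconds() / 3600.0
        if hours <= min_hours:
            continue
        if best is not None and note.ts >= best[0]:
            continue
        for mention in scan_note(note, lex):
            if not mention.negated:
                best = (note.ts, mention)
                break
    return best


def mentions_to_frame(mentions: Iterable[PIMention]):
    """Tidy CSV-ready view of mentions (note_id, stay_id, span, phrase, ...)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "note_id": m.note_id, "stay_id": m.stay_id, "start": m.start,
                "end": m.end, "phrase": m.phrase, "negated": m.negated,
                "ts": m.ts, "date_only": m.date_only,
            }
            for m in mentions
        ],
        columns=["note_id", "stay_id", "start", "end", "phrase", "negated", "ts", "date_only"],
    )
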