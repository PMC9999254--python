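"""Pressure-injury stage extraction from chart events and staging semantics.

PI severity is documented as numeric stages 1-4 plus two categories without a
visible numeric stage: deep tissue injury (DTI) and unstageable (depth
obscured by slough/eschar).  The staging route of a HAPI definition compares
an *admission stage* (worst stage documented inside the admission window)
with a *discharge stage* (last qualifying stage documented after the window)
under asymmetric integer encodings:

===========  =========  =========
token        admission  discharge
===========  =========  =========
stage 1-4    1-4        1-4
DTI          4          3
unstageable  0          5
absent       0          (absent)
===========  =========  =========

DTI is encoded 4 at admission and 3 at discharge so that a DTI documented on
both ends counts as an improvement and is excluded when only new/worsened
PIs qualify; unstageable is 5 at discharge so it always captures a possible
HAPI regardless of the admission stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .ehr_model import ChartEvent, HospitalStay


class StageToken(Enum):
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    S4 = "S4"
    DTI = "DTI"
    UNSTAGEABLE = "UNSTAGEABLE"


NUMERIC_TOKENS = frozenset({StageToken.S1, StageToken.S2, StageToken.S3, StageToken.S4})


@dataclass(frozen=True)
class PIStagingEvent:
    stay_id: str
    hours_from_admission: float
    token: StageToken
    raw_value: str
    item_id: str

    def __post_init__(self):
        if self.hours_from_admission < 0:
            raise ValueError("staging event precedes admission")


@dataclass(frozen=True)
class StageEncoding:
    """Admission/discharge integer encodings; total over the token enum."""

    admission_map: dict = field(default_factory=lambda: {
        StageToken.S1: 1, StageToken.S2: 2, StageToken.S3: 3, StageToken.S4: 4,
        StageToken.DTI: 4, StageToken.UNSTAGEABLE: 0,
    })
    discharge_map: dict = field(default_factory=lambda: {
        StageToken.S1: 1, StageToken.S2: 2, StageToken.S3: 3, StageToken.S4: 4,
        StageToken.DTI: 3, StageToken.UNSTAGEABLE: 5,
    })
    absent_admission_value: int = 0

    def __post_init__(self):
        for m in (self.admission_map, self.discharge_map):
            missing = set(StageToken) - set(m)
            if missing:
                raise ValueError(f"encoding not total over StageToken: missing {missing}")


DEFAULT_ENCODING = StageEncoding()


@dataclass(frozen=True)
class StageMapEntry:
    item_id: str
    value_regex: str
    token: StageToken


# Emulated default map for MIMIC CareVue/Metavision PI staging items.  The
# item ids below follow the CareVue "Pressure Sore [Stage]" (551-553) and
# Metavision "Pressure Ulcer Stage" (224631) conventions; value patterns are
# matched case-insensitively anywhere in the charted value string.  Override
# with a YAML map for a specific export.
_PI_ITEM_IDS = ("551", "552", "553", "224631", "224965", "224966")
_VALUE_PATTERNS: Sequence[tuple[str, StageToken]] = (
    (r"deep\s*tiss", StageToken.DTI),
    (r"unable\s*to\s*stage|unstage", StageToken.UNSTAGEABLE),
    (r"(?:stage\s*)?(?:1|I)\b|partial\s+thickness", StageToken.S1),
    (r"(?:stage\s*)?(?:2|II)\b", StageToken.S2),
    (r"(?:stage\s*)?(?:3|III)\b", StageToken.S3),
    (r"(?:stage\s*)?(?:4|IV)\b", StageToken.S4),
)


def default_stage_item_map() -> list[StageMapEntry]:
    return [
        StageMapEntry(item, pat, tok)
        for item in _PI_ITEM_IDS
        for pat, tok in _VALUE_PATTERNS
    ]


def stage_item_map_from_config(entries: Iterable[dict]) -> list[StageMapEntry]:
    """Build a map from ``[{item_id, value_regex, token}, ...]`` dicts (YAML)."""
    out = []
    for e in entries:
        out.append(StageMapEntry(str(e["item_id"]), e["value_regex"], StageToken[e["token"]]))
    return out


def extract_staging_events(
    chart_events: Iterable[ChartEvent],
    stay: HospitalStay,
    stage_item_map: Sequence[StageMapEntry],
) -> tuple[list[PIStagingEvent], int]:
    """Map raw chart events to canonical PI staging events.

    Only events whose item_id appears in the map are considered; patterns for
    that item are tried in map order and the first match wins.  Events on
    mapped items whose value matches no pattern are dropped and counted in
    the returned warning count.  Events charted before admission are dropped
    the same way (the staging timeline is anchored at admission).
    """
    if not stage_item_map:
        raise ValueError("stage_item_map is empty: cannot silently produce zero PI evidence")
    by_item: dict[str, list[tuple[re.Pattern, StageToken]]] = {}
    for entry in stage_item_map:
        by_item.setdefault(entry.item_id, []).append(
            (re.compile(entry.value_regex, re.IGNORECASE), entry.token))

    events: list[PIStagingEvent] = []
    unmapped_values = 0
    for ev in chart_events:
        patterns = by_item.get(str(ev.item_id))
        if patterns is None:
            continue
        token = next((tok for rx, tok in patterns if rx.search(ev.value_text or "")), None)
        hours = stay.hours_from_admission(ev.ts)
        if token is None or hours < 0:
            unmapped_values += 1
            continue
        events.append(PIStagingEvent(ev.stay_id, hours, token, ev.value_text, str(ev.item_id)))
    events.sort(key=lambda e: e.hours_from_admission)
    return events, unmapped_values


def filter_tokens(
    events: Iterable[PIStagingEvent], include_dti_unstageable: bool
) -> list[PIStagingEvent]:
    """Drop DTI/unstageable events when a definition disables them (D5)."""
    if include_dti_unstageable:
        return list(events)
    return [e for e in events if e.token in NUMERIC_TOKENS]


def admission_stage(
    events: Iterable[PIStagingEvent],
    cutoff_hours: float,
    enc: StageEncoding = DEFAULT_ENCODING,
) -> int:
    """Worst encoded stage documented within the admission window.

    Aggregates by max of the admission encoding over events with
    ``hours <= cutoff_hours`` (closed window).  With no qualifying event the
    stage is 0: absence of admission staging information means no documented
    admission PI.
    """
    if cutoff_hours < 0:
        raise ValueError("cutoff_hours must be >= 0")
    vals = [enc.admission_map[e.token] for e in events if e.hours_from_admission <= cutoff_hours]
    return max(vals, default=enc.absent_admission_value)


def discharge_stage(
    events: Iterable[PIStagingEvent],
    cutoff_hours: float,
    enc: StageEncoding = DEFAULT_ENCODING,
    min_numeric: int = 2,
) -> Optional[int]:
    """Last qualifying encoded stage documented after the admission window.

    Qualifying events have ``hours > cutoff_hours`` (strict) and encoded
    discharge value >= ``min_numeric``; the latest such event's value is
    returned (ties at an identical timestamp resolve to the max encoded
    value, making the result order-independent).  None when nothing
    qualifies.
    """
    if cutoff_hours < 0:
        raise ValueError("cutoff_hours must be >= 0")
    best: Optional[tuple[float, int]] = None  # (hours, encoded)
    for e in events:
        if e.hours_from_admission <= cutoff_hours:
            continue
        val = enc.discharge_map[e.token]
        if val < min_numeric:
            continue
        if best is None or e.hours_from_admission > best[0] or (
            e.hours_from_admission == best[0] and val > best[1]
        ):
            best = (e.hours_from_admission, val)
    return None if best is None else best[1]


def staging_case_decision(
    adm: int,
    disch: Optional[int],
    require_deterioration: bool,
    min_stage: int,
) -> bool:
    """HAPI decision for the staging route.

    With deterioration required (new or worsened PI only), the discharge
    stage must both reach the minimum stage and strictly exceed the
    admission stage; otherwise reaching the minimum stage suffices.
    """
    if adm < 0:
        raise ValueError("admission stage must be >= 0")
    if disch is None:
        return False
    if require_deterioration:
        return disch >= min_stage and disch > adm
    return disch >= min_stage
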