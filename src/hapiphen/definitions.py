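"""HAPI case-definition policies and the per-stay labeling engine.

A hospital-acquired pressure injury (HAPI) case definition is a labeling
policy over one hospital stay's EHR evidence.  Published MIMIC-III policies
differ along eight decision dimensions:

D1  exclude in-hospital deaths            D5  count DTI / unstageable events
D2  minimum age in years                  D6  use PI keywords in notes
D3  admission-window cutoff (24/48 h)     D7  require new or worsened PI
D4  minimum numeric PI stage              D8  use ICD-9 diagnosis codes

:class:`DefinitionConfig` captures a policy as those dimensions plus routing
flags; :func:`builtin_definitions` ships the four policies compared in this
package (EHAPI, CANTRIP, Cramer, Sotoodeh).  Labeling partitions every stay
into exactly one of case / control / excluded, and records for each case the
evidence route that fired and, when the route is timed, the event timestamp
(the first PI assessment, used downstream for leakage-safe features).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ehr_model import ClinicalNote, CohortStore, DiagnosisCode, HospitalStay
from .pi_staging import (
    DEFAULT_ENCODING,
    PIStagingEvent,
    StageEncoding,
    StageMapEntry,
    admission_stage,
    default_stage_item_map,
    discharge_stage,
    extract_staging_events,
    filter_tokens,
    NUMERIC_TOKENS,
)
from .pi_text import KeywordLexicon, earliest_positive_mention, scan_note

#: Default PI ICD-9 prefixes: 707.0x (pressure ulcer by site) and 707.25
#: (stage-coded pressure ulcer).  MIMIC-level counts depend on the exact
#: configured list; override per export.
DEFAULT_ICD9_PREFIXES = ("7070", "70725")

#: The note-based admission-PI screen always uses a 24 h window, independent
#: of a definition's staging cutoff.
NOTE_SCREEN_HOURS = 24.0


@dataclass(frozen=True)
class DefinitionConfig:
    """One HAPI labeling policy (the eight dimensions plus routing flags)."""

    name: str
    exclude_deceased: bool                      # D1
    min_age_years: int                          # D2
    admission_cutoff_hours: Optional[float]     # D3 (None when staging unused)
    min_stage: Optional[int]                    # D4
    include_dti_unstageable: bool               # D5
    use_note_keywords: bool                     # D6
    require_deterioration: bool                 # D7
    use_icd9: bool                              # D8
    use_staging_events: bool = True
    icd9_codes: Sequence[str] = DEFAULT_ICD9_PREFIXES
    #: Notes lacking a time component qualify for the keyword route unless a
    #: definition requires time-stamped notes (CANTRIP).
    keyword_include_date_only: bool = True

    def __post_init__(self):
        if self.use_staging_events and (
            self.admission_cutoff_hours is None or self.min_stage is None
        ):
            raise ValueError(
                f"{self.name}: staging route enabled but admission_cutoff_hours/min_stage unset")

    @property
    def keyword_cutoff_hours(self) -> float:
        """Mentions must occur strictly later than this to fire the keyword
        route; the staging cutoff when present, else the 24 h note screen."""
        if self.admission_cutoff_hours is not None:
            return self.admission_cutoff_hours
        return NOTE_SCREEN_HOURS

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["icd9_codes"] = list(self.icd9_codes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DefinitionConfig":
        d = dict(d)
        if "icd9_codes" in d:
            d["icd9_codes"] = tuple(d["icd9_codes"])
        return cls(**d)


def builtin_definitions() -> list[DefinitionConfig]:
    """The four built-in policies, in canonical order.

    EHAPI excludes in-hospital deaths and requires a new or worsened PI;
    CANTRIP uses a 48 h window and any stage >= 1; Cramer uses staging chart
    events only and drops DTI/unstageable; Sotoodeh uses ICD-9 codes and
    note keywords without a staging timeline.
    """
    return [
        DefinitionConfig(
            name="ehapi", exclude_deceased=True, min_age_years=15,
            admission_cutoff_hours=24.0, min_stage=2, include_dti_unstageable=True,
            use_note_keywords=True, require_deterioration=True, use_icd9=False,
        ),
        DefinitionConfig(
            name="cantrip", exclude_deceased=False, min_age_years=15,
            admission_cutoff_hours=48.0, min_stage=1, include_dti_unstageable=True,
            use_note_keywords=True, require_deterioration=False, use_icd9=False,
            keyword_include_date_only=False,
        ),
        DefinitionConfig(
            name="cramer", exclude_deceased=False, min_age_years=18,
            admission_cutoff_hours=24.0, min_stage=2, include_dti_unstageable=False,
            use_note_keywords=False, require_deterioration=False, use_icd9=False,
        ),
        DefinitionConfig(
            name="sotoodeh", exclude_deceased=False, min_age_years=18,
            admission_cutoff_hours=None, min_stage=None, include_dti_unstageable=False,
            use_note_keywords=True, require_deterioration=False, use_icd9=True,
            use_staging_events=False,
        ),
    ]


def get_definition(name: str) -> DefinitionConfig:
    for cfg in builtin_definitions():
        if cfg.name == name.lower():
            return cfg
    raise KeyError(f"unknown definition {name!r}; builtins: ehapi, cantrip, cramer, sotoodeh")


@dataclass(frozen=True)
class StayLabel:
    stay_id: str
    status: str                         # case | control | excluded
    route: str = "none"                 # staging | keyword | icd9 | none
    event_ts: Optional[datetime] = None
    exclusion_reason: Optional[str] = None

    def __post_init__(self):
        if self.status == "case" and self.route == "none":
            raise ValueError("a case must carry the route that fired")
        if self.status == "excluded" and not self.exclusion_reason:
            raise ValueError("an excluded stay must carry a reason")


def check_common_inclusion(
    stay: HospitalStay,
    notes: Sequence[ClinicalNote],
    staging_events: Sequence[PIStagingEvent],
    cfg: DefinitionConfig,
    lex: Optional[KeywordLexicon] = None,
) -> Optional[str]:
    """First failing common inclusion criterion, or None when eligible.

    Checks, in order: at least one clinical note; discharge after admission;
    minimum age (missing age excludes); no PI documented on admission — a
    numeric stage 1-4 charted inside the admission window, or, for keyword
    definitions, a non-negated mention within 24 h; and, for policies that
    exclude in-hospital deaths, death during the stay.
    """
    if not any((n.text or "").strip() for n in notes):
        return "no_notes"
    if stay.discharge_ts <= stay.admit_ts:
        return "bad_times"
    if stay.age_at_admission is None:
        return "missing_age"
    if stay.age_at_admission < cfg.min_age_years:
        return "under_age"

    cutoff = cfg.admission_cutoff_hours
    if cfg.use_staging_events and cutoff is not None:
        # Only numeric stages trigger the admission screen; admission DTI and
        # unstageable events flow into the stage-encoding deterioration logic
        # instead (an unstageable PI on admission that is later staged still
        # counts as hospital-acquired).
        for ev in staging_events:
            if ev.token in NUMERIC_TOKENS and ev.hours_from_admission <= cutoff:
                return "pi_on_admission"
    if cfg.use_note_keywords and lex is not None:
        for note in notes:
            if note.ts is None:
                continue
            hours = stay.hours_from_admission(note.ts)
            if hours > NOTE_SCREEN_HOURS:
                continue
            if any(not m.negated for m in scan_note(note, lex)):
                return "pi_on_admission"

    if cfg.exclude_deceased and stay.died_in_hospital:
        return "deceased"
    return None


def label_stay(
    stay: HospitalStay,
    staging_events: Sequence[PIStagingEvent],
    notes: Sequence[ClinicalNote],
    dx_codes: Sequence[DiagnosisCode],
    cfg: DefinitionConfig,
    lex: Optional[KeywordLexicon] = None,
    enc: StageEncoding = DEFAULT_ENCODING,
) -> StayLabel:
    """Label one eligible stay under a policy (flowchart semantics).

    A stay is a case when any enabled route fires: the staging route
    (admission/discharge stage comparison), the keyword route (earliest
    positive mention beyond the cutoff) or the ICD-9 route (any configured
    code prefix).  ``event_ts`` is the earliest timestamp among firing timed
    routes; the ICD-9 route is untimed.  Common inclusion must have been
    checked already.
    """
    firing: list[tuple[str, Optional[datetime]]] = []

    if cfg.use_staging_events:
        cutoff = cfg.admission_cutoff_hours
        events = filter_tokens(staging_events, cfg.include_dti_unstageable)
        adm = admission_stage(events, cutoff, enc)
        disch = discharge_stage(events, cutoff, enc, min_numeric=cfg.min_stage)
        if staging_case_decision_cfg(adm, disch, cfg):
            first_ev = min(
                (e for e in events if e.hours_from_admission > cutoff
                 and enc.discharge_map[e.token] >= cfg.min_stage),
                key=lambda e: e.hours_from_admission,
            )
            firing.append(("staging", _ts_at(stay, first_ev.hours_from_admission)))

    if cfg.use_note_keywords and lex is not None:
        hit = earliest_positive_mention(
            notes, lex, cfg.keyword_cutoff_hours, stay.admit_ts,
            include_date_only=cfg.keyword_include_date_only,
        )
        if hit is not None:
            firing.append(("keyword", hit[0]))

    if cfg.use_icd9:
        prefixes = tuple(cfg.icd9_codes)
        if any(d.code.startswith(prefixes) for d in dx_codes):
            firing.append(("icd9", None))

    if not firing:
        return StayLabel(stay.stay_id, "control")

    timed = [(ts, route) for route, ts in firing if ts is not None]
    if timed:
        event_ts, route = min(timed, key=lambda x: x[0])
        return StayLabel(stay.stay_id, "case", route=route, event_ts=event_ts)
    # only the untimed ICD-9 route fired
    return StayLabel(stay.stay_id, "case", route=firing[0][0], event_ts=None)


def staging_case_decision_cfg(adm: int, disch: Optional[int], cfg: DefinitionConfig) -> bool:
    from .pi_staging import staging_case_decision

    return staging_case_decision(adm, disch, cfg.require_deterioration, cfg.min_stage)


def _ts_at(stay: HospitalStay, hours: float) -> datetime:
    from datetime import timedelta

    return stay.admit_ts + timedelta(hours=hours)


@dataclass
class CohortLabeling:
    """Per-stay labels plus the eligibility/prevalence summary."""

    definition: str
    labels: pd.DataFrame  # stay_id, status, route, event_ts, exclusion_reason
    n_stays: int
    n_eligible: int
    n_cases: int

    @property
    def prevalence_pct(self) -> float:
        return 100.0 * self.n_cases / self.n_eligible if self.n_eligible else 0.0

    def case_ids(self) -> set[str]:
        return set(self.labels.loc[self.labels["status"] == "case", "stay_id"])

    def summary(self) -> dict:
        return {
            "definition": self.definition,
            "n_stays": self.n_stays,
            "n_eligible": self.n_eligible,
            "n_cases": self.n_cases,
            "prevalence_pct": self.prevalence_pct,
        }


def label_cohort(
    store: CohortStore,
    cfg: DefinitionConfig,
    lex: Optional[KeywordLexicon] = None,
    stage_item_map: Optional[Sequence[StageMapEntry]] = None,
    enc: StageEncoding = DEFAULT_ENCODING,
) -> CohortLabeling:
    """Label every stay in a cohort under one policy.

    Prevalence is cases over eligible stays (excluded stays leave the
    denominator).  Deterministic: the same store and config always produce
    an identical label table.
    """
    if lex is None:
        lex = KeywordLexicon()
    if stage_item_map is None:
        stage_item_map = default_stage_item_map()

    rows = []
    for sid in sorted(store.stays):
        stay = store.stays[sid]
        notes = store.notes_for(sid)
        events, _ = extract_staging_events(store.events_for(sid), stay, stage_item_map)
        reason = check_common_inclusion(stay, notes, events, cfg, lex=lex)
        if reason is not None:
            label = StayLabel(sid, "excluded", exclusion_reason=reason)
        else:
            label = label_stay(stay, events, notes, store.diagnoses_for(sid), cfg, lex=lex, enc=enc)
        rows.append({
            "stay_id": label.stay_id,
            "status": label.status,
            "route": label.route,
            "event_ts": label.event_ts,
            "exclusion_reason": label.exclusion_reason,
        })
    df = pd.DataFrame(rows, columns=["stay_id", "status", "route", "event_ts", "exclusion_reason"])
    n_eligible = int((df["status"] != "excluded").sum())
    n_cases = int((df["status"] == "case").sum())
    return CohortLabeling(cfg.name, df, len(df), n_eligible, n_cases)


def label_all_definitions(
    store: CohortStore,
    configs: Optional[Iterable[DefinitionConfig]] = None,
    lex: Optional[KeywordLexicon] = None,
    stage_item_map: Optional[Sequence[StageMapEntry]] = None,
) -> dict[str, CohortLabeling]:
    configs = list(configs) if configs is not None else builtin_definitions()
    return {
        cfg.name: label_cohort(store, cfg, lex=lex, stage_item_map=stage_item_map)
        for cfg in configs
    }
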