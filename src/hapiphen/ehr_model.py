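"""Domain types and CSV readers for MIMIC-III-schema EHR tables.

The four data sources that can document a pressure injury (PI) during a
hospital stay are chart events (timed, structured nursing assessments),
clinical notes (free text), diagnosis codes (untimed, billing-level ICD-9)
and procedure codes.  This module loads those tables from CSV files into an
indexed per-stay :class:`CohortStore` that the labeling engine operates on.

All relative times are expressed as float hours from hospital admission.
Timestamps are parsed as naive datetimes (MIMIC carries no timezone).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

#: Ages above this are treated as obfuscated (MIMIC shifts DOBs of patients
#: older than 89) and clamped to AGE_CAP_YEARS.
AGE_OBFUSCATION_THRESHOLD = 120.0
AGE_CAP_YEARS = 90.0

HOURS_PER_YEAR = 365.25 * 24.0


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_ts: Optional[datetime]
    death_ts: Optional[datetime] = None


@dataclass(frozen=True)
class HospitalStay:
    """One hospital admission — the unit of HAPI labeling."""

    stay_id: str
    patient_id: str
    admit_ts: datetime
    discharge_ts: datetime
    died_in_hospital: bool
    age_at_admission: Optional[float]  # years; None when DOB is missing

    @property
    def duration_hours(self) -> float:
        return (self.discharge_ts - self.admit_ts).total_seconds() / 3600.0

    def hours_from_admission(self, ts: datetime) -> float:
        return (ts - self.admit_ts).total_seconds() / 3600.0


@dataclass(frozen=True)
class ChartEvent:
    stay_id: str
    ts: datetime
    item_id: str
    value_text: str


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    stay_id: str
    ts: Optional[datetime]
    category: str
    text: str
    #: True when the source row had only a charting date; the timestamp is
    #: the date at 00:00 and hour-resolution comparisons are conservative.
    date_only: bool = False


@dataclass(frozen=True)
class DiagnosisCode:
    stay_id: str
    code: str
    seq: int


@dataclass(frozen=True)
class ProcedureCode:
    stay_id: str
    code: str
    ts: Optional[datetime] = None


# Logical-field -> column-name map for MIMIC-III v1.4 CSV exports.  A schema
# config (dict or YAML) with the same nesting overrides individual entries so
# non-MIMIC exports can be ingested.
DEFAULT_SCHEMA: dict[str, dict[str, str]] = {
    "admissions": {
        "stay_id": "HADM_ID",
        "patient_id": "SUBJECT_ID",
        "admit_ts": "ADMITTIME",
        "discharge_ts": "DISCHTIME",
        "death_ts": "DEATHTIME",
    },
    "patients": {
        "patient_id": "SUBJECT_ID",
        "birth_ts": "DOB",
        "death_ts": "DOD",
    },
    "icustays": {
        "stay_id": "HADM_ID",
        "icustay_id": "ICUSTAY_ID",
        "in_ts": "INTIME",
        "out_ts": "OUTTIME",
    },
    "chartevents": {
        "stay_id": "HADM_ID",
        "ts": "CHARTTIME",
        "item_id": "ITEMID",
        "value_text": "VALUE",
    },
    "noteevents": {
        "note_id": "ROW_ID",
        "stay_id": "HADM_ID",
        "ts": "CHARTTIME",
        "date": "CHARTDATE",
        "category": "CATEGORY",
        "text": "TEXT",
    },
    "diagnoses_icd": {
        "stay_id": "HADM_ID",
        "code": "ICD9_CODE",
        "seq": "SEQ_NUM",
    },
    "procedures_icd": {
        "stay_id": "HADM_ID",
        "code": "ICD9_CODE",
    },
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class LoadReport:
    """Row-level accounting from :func:`load_cohort`."""

    dropped_orphans: dict[str, int] = field(default_factory=dict)
    dropped_bad_timestamps: dict[str, int] = field(default_factory=dict)
    date_only_notes: int = 0


@dataclass
class CohortStore:
    """Indexed per-stay view of a cohort.

    Child record lists are sorted by timestamp (untimed records last) and
    referential integrity holds: every child stay_id resolves to a stay.
    """

    stays: dict[str, HospitalStay] = field(default_factory=dict)
    patients: dict[str, Patient] = field(default_factory=dict)
    chart_events: dict[str, list[ChartEvent]] = field(default_factory=dict)
    notes: dict[str, list[ClinicalNote]] = field(default_factory=dict)
    diagnoses: dict[str, list[DiagnosisCode]] = field(default_factory=dict)
    procedures: dict[str, list[ProcedureCode]] = field(default_factory=dict)
    report: LoadReport = field(default_factory=LoadReport)

    def stay_ids(self) -> list[str]:
        return list(self.stays)

    def events_for(self, stay_id: str) -> list[ChartEvent]:
        return self.chart_events.get(stay_id, [])

    def notes_for(self, stay_id: str) -> list[ClinicalNote]:
        return self.notes.get(stay_id, [])

    def diagnoses_for(self, stay_id: str) -> list[DiagnosisCode]:
        return self.diagnoses.get(stay_id, [])

    def procedures_for(self, stay_id: str) -> list[ProcedureCode]:
        return self.procedures.get(stay_id, [])


def compute_age(
    birth_ts: Optional[datetime],
    admit_ts: datetime,
    cap_years: float = AGE_CAP_YEARS,
) -> Optional[float]:
    """Age in years at admission; obfuscated ages (> 120 y) clamp to the cap.

    Returns None when the birth timestamp is missing, in which case the stay
    is excluded downstream with reason ``missing_age``.
    """
    if birth_ts is None:
        return None
    age = (admit_ts - birth_ts).total_seconds() / 3600.0 / HOURS_PER_YEAR
    if age > AGE_OBFUSCATION_THRESHOLD:
        return float(cap_years)
    return float(age)


def _merged_schema(schema_config: Optional[Mapping] = None) -> dict:
    schema = {t: dict(cols) for t, cols in DEFAULT_SCHEMA.items()}
    if schema_config:
        for table, cols in schema_config.items():
            schema.setdefault(table, {}).update(cols)
    return schema


def _read_table(path, table: str, needed: Iterable[str], colmap: Mapping[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    for logical in needed:
        col = colmap[logical]
        if col not in df.columns:
            raise SchemaError(f"table {table!r}: required column {col!r} (field {logical!r}) missing")
    return df


def _parse_ts(value) -> Optional[datetime]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    ts = pd.to_datetime(value, errors="coerce")
    if pd.isna(ts):
        return None
    return ts.to_pydatetime()


def load_cohort(
    table_paths: Mapping[str, "str | Path"],
    schema_config: Optional[Mapping] = None,
    age_cap_years: float = AGE_CAP_YEARS,
) -> CohortStore:
    """Load MIMIC-III-schema CSV tables into an indexed :class:`CohortStore`.

    Parameters
    ----------
    table_paths
        Mapping from logical table name (``admissions``, ``patients``,
        ``chartevents``, ``noteevents``, ``diagnoses_icd``,
        ``procedures_icd``, optionally ``icustays``) to a CSV path.  Only
        ``admissions`` is mandatory; absent tables yield empty stores.
    schema_config
        Optional per-table logical-field -> column-name overrides.

    Child records whose stay_id does not resolve to a loaded admission are
    dropped and counted in ``store.report.dropped_orphans``; rows with
    unparseable timestamps are dropped and counted likewise.
    """
    schema = _merged_schema(schema_config)
    store = CohortStore()

    if "admissions" not in table_paths:
        raise SchemaError("table_paths must include 'admissions'")

    # patients first so ages can be computed during the admissions pass
    if "patients" in table_paths:
        cm = schema["patients"]
        df = _read_table(table_paths["patients"], "patients", ["patient_id"], cm)
        for row in df.itertuples(index=False):
            rec = row._asdict()
            pid = str(rec[cm["patient_id"]])
            birth = _parse_ts(rec.get(cm.get("birth_ts", ""), None))
            death = _parse_ts(rec.get(cm.get("death_ts", ""), None))
            store.patients[pid] = Patient(pid, birth, death)

    cm = schema["admissions"]
    df = _read_table(
        table_paths["admissions"], "admissions",
        ["stay_id", "patient_id", "admit_ts", "discharge_ts"], cm,
    )
    bad_ts = 0
    for row in df.itertuples(index=False):
        rec = row._asdict()
        sid = str(rec[cm["stay_id"]])
        pid = str(rec[cm["patient_id"]])
        admit = _parse_ts(rec.get(cm["admit_ts"]))
        disch = _parse_ts(rec.get(cm["discharge_ts"]))
        if admit is None or disch is None:
            bad_ts += 1
            continue
        death = _parse_ts(rec.get(cm.get("death_ts", ""), None))
        died = death is not None and admit <= death <= disch
        patient = store.patients.get(pid)
        age = compute_age(patient.birth_ts if patient else None, admit, cap_years=age_cap_years)
        store.stays[sid] = HospitalStay(sid, pid, admit, disch, died, age)
    if bad_ts:
        store.report.dropped_bad_timestamps["admissions"] = bad_ts
        logger.warning("admissions: dropped %d rows with unparseable timestamps", bad_ts)

    def _track(table: str, orphans: int, badts: int) -> None:
        if orphans:
            store.report.dropped_orphans[table] = orphans
            logger.warning("%s: dropped %d rows with unresolvable stay_id", table, orphans)
        if badts:
            store.report.dropped_bad_timestamps[table] = badts
            logger.warning("%s: dropped %d rows with unparseable timestamps", table, badts)

    if "chartevents" in table_paths:
        cm = schema["chartevents"]
        df = _read_table(table_paths["chartevents"], "chartevents",
                         ["stay_id", "ts", "item_id", "value_text"], cm)
        by_stay: dict[str, list[ChartEvent]] = defaultdict(list)
        orphans = badts = 0
        for row in df.itertuples(index=False):
            rec = row._asdict()
            sid = str(rec[cm["stay_id"]])
            if sid not in store.stays:
                orphans += 1
                continue
            ts = _parse_ts(rec.get(cm["ts"]))
            if ts is None:
                badts += 1  # chart events are timed by contract
                continue
            value = rec.get(cm["value_text"])
            by_stay[sid].append(ChartEvent(sid, ts, str(rec[cm["item_id"]]),
                                           "" if pd.isna(value) else str(value)))
        store.chart_events = {s: sorted(evs, key=lambda e: e.ts) for s, evs in by_stay.items()}
        _track("chartevents", orphans, badts)

    if "noteevents" in table_paths:
        cm = schema["noteevents"]
        df = _read_table(table_paths["noteevents"], "noteevents",
                         ["note_id", "stay_id", "text"], cm)
        by_stay_n: dict[str, list[ClinicalNote]] = defaultdict(list)
        orphans = badts = date_only = 0
        for row in df.itertuples(index=False):
            rec = row._asdict()
            sid = str(rec[cm["stay_id"]])
            if sid not in store.stays:
                orphans += 1
                continue
            ts = _parse_ts(rec.get(cm.get("ts", ""), None))
            is_date_only = False
            if ts is None:
                # MIMIC NOTEEVENTS has date-only rows: assign the date at
                # 00:00 and flag; flagged notes are scanned for keywords but
                # never create hour-resolution events on their own merits.
                ts = _parse_ts(rec.get(cm.get("date", ""), None))
                if ts is not None:
                    is_date_only = True
                    date_only += 1
            if ts is None:
                badts += 1
                continue
            text = rec.get(cm["text"])
            text = "" if pd.isna(text) else str(text)
            category = str(rec.get(cm.get("category", ""), "") or "")
            by_stay_n[sid].append(
                ClinicalNote(str(rec[cm["note_id"]]), sid, ts, category, text, is_date_only)
            )
        store.notes = {s: sorted(ns, key=lambda n: n.ts) for s, ns in by_stay_n.items()}
        store.report.date_only_notes = date_only
        _track("noteevents", orphans, badts)

    if "diagnoses_icd" in table_paths:
        cm = schema["diagnoses_icd"]
        df = _read_table(table_paths["diagnoses_icd"], "diagnoses_icd", ["stay_id", "code"], cm)
        by_stay_d: dict[str, list[DiagnosisCode]] = defaultdict(list)
        orphans = 0
        for row in df.itertuples(index=False):
            rec = row._asdict()
            sid = str(rec[cm["stay_id"]])
            if sid not in store.stays:
                orphans += 1
                continue
            code = rec.get(cm["code"])
            if code is None or pd.isna(code) or str(code) == "":
                continue
            seq_raw = rec.get(cm.get("seq", ""), None)
            try:
                seq = int(float(seq_raw)) if seq_raw not in (None, "") else 0
            except (TypeError, ValueError):
                seq = 0
            by_stay_d[sid].append(DiagnosisCode(sid, str(code), seq))
        store.diagnoses = {s: sorted(ds, key=lambda d: d.seq) for s, ds in by_stay_d.items()}
        _track("diagnoses_icd", orphans, 0)

    if "procedures_icd" in table_paths:
        cm = schema["procedures_icd"]
        df = _read_table(table_paths["procedures_icd"], "procedures_icd", ["stay_id", "code"], cm)
        by_stay_p: dict[str, list[ProcedureCode]] = defaultdict(list)
        orphans = 0
        for row in df.itertuples(index=False):
            rec = row._asdict()
            sid = str(rec[cm["stay_id"]])
            if sid not in store.stays:
                orphans += 1
                continue
            ts = _parse_ts(rec.get(cm.get("ts", ""), None))
            by_stay_p[sid].append(ProcedureCode(sid, str(rec[cm["code"]]), ts))
        store.procedures = dict(by_stay_p)
        _track("procedures_icd", orphans, 0)

    return store


TS_FMT = "%Y-%m-%d %H:%M:%S"


def _fmt(ts: Optional[datetime]) -> str:
    return "" if ts is None else ts.strftime(TS_FMT)


def write_tables(store: CohortStore, out_dir: "str | Path") -> dict[str, Path]:
    """Write the store back out as MIMIC-III-schema CSV tables.

    Round-trip guarantee: ``load_cohort(write_tables(store))`` reproduces the
    per-table record counts of ``store``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = [
        {
            "HADM_ID": s.stay_id,
            "SUBJECT_ID": s.patient_id,
            "ADMITTIME": _fmt(s.admit_ts),
            "DISCHTIME": _fmt(s.discharge_ts),
            "DEATHTIME": _fmt(s.discharge_ts) if s.died_in_hospital else "",
        }
        for s in store.stays.values()
    ]
    paths["admissions"] = out / "ADMISSIONS.csv"
    pd.DataFrame(rows, columns=["HADM_ID", "SUBJECT_ID", "ADMITTIME", "DISCHTIME", "DEATHTIME"]).to_csv(
        paths["admissions"], index=False)

    rows = [
        {"SUBJECT_ID": p.patient_id, "DOB": _fmt(p.birth_ts), "DOD": _fmt(p.death_ts)}
        for p in store.patients.values()
    ]
    paths["patients"] = out / "PATIENTS.csv"
    pd.DataFrame(rows, columns=["SUBJECT_ID", "DOB", "DOD"]).to_csv(paths["patients"], index=False)

    rows = [
        {"HADM_ID": e.stay_id, "CHARTTIME": _fmt(e.ts), "ITEMID": e.item_id, "VALUE": e.value_text}
        for evs in store.chart_events.values() for e in evs
    ]
    paths["chartevents"] = out / "CHARTEVENTS.csv"
    pd.DataFrame(rows, columns=["HADM_ID", "CHARTTIME", "ITEMID", "VALUE"]).to_csv(
        paths["chartevents"], index=False)

    rows = [
        {
            "ROW_ID": n.note_id,
            "HADM_ID": n.stay_id,
            "CHARTDATE": "" if n.ts is None else n.ts.strftime("%Y-%m-%d"),
            "CHARTTIME": "" if n.date_only else _fmt(n.ts),
            "CATEGORY": n.category,
            "TEXT": n.text,
        }
        for ns in store.notes.values() for n in ns
    ]
    paths["noteevents"] = out / "NOTEEVENTS.csv"
    pd.DataFrame(rows, columns=["ROW_ID", "HADM_ID", "CHARTDATE", "CHARTTIME", "CATEGORY", "TEXT"]).to_csv(
        paths["noteevents"], index=False)

    rows = [
        {"HADM_ID": d.stay_id, "SEQ_NUM": d.seq, "ICD9_CODE": d.code}
        for ds in store.diagnoses.values() for d in ds
    ]
    paths["diagnoses_icd"] = out / "DIAGNOSES_ICD.csv"
    pd.DataFrame(rows, columns=["HADM_ID", "SEQ_NUM", "ICD9_CODE"]).to_csv(
        paths["diagnoses_icd"], index=False)

    rows = [
        {"HADM_ID": p.stay_id, "ICD9_CODE": p.code}
        for ps in store.procedures.values() for p in ps
    ]
    paths["procedures_icd"] = out / "PROCEDURES_ICD.csv"
    pd.DataFrame(rows, columns=["HADM_ID", "ICD9_CODE"]).to_csv(paths["procedures_icd"], index=False)

    return paths


def store_from_records(
    stays: Iterable[HospitalStay],
    patients: Iterable[Patient] = (),
    chart_events: Iterable[ChartEvent] = (),
    notes: Iterable[ClinicalNote] = (),
    diagnoses: Iterable[DiagnosisCode] = (),
    procedures: Iterable[ProcedureCode] = (),
) -> CohortStore:
    """Assemble a store from in-memory records (orphans are rejected)."""
    store = CohortStore()
    store.stays = {s.stay_id: s for s in stays}
    store.patients = {p.patient_id: p for p in patients}

    def _index(records, sort_key):
        by: dict[str, list] = defaultdict(list)
        for r in records:
            if r.stay_id not in store.stays:
                raise ValueError(f"orphan record for stay {r.stay_id!r}")
            by[r.stay_id].append(r)
        for sid in by:
            by[sid].sort(key=sort_key)
        return dict(by)

    def _by_ts(r):
        return (r.ts is None, r.ts or datetime.min)

    store.chart_events = _index(chart_events, _by_ts)
    store.notes = _index(notes, _by_ts)
    store.diagnoses = _index(diagnoses, lambda d: d.seq)
    store.procedures = _index(procedures, _by_ts)
    return store
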