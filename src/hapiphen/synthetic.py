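"""Synthetic MIMIC-III-schema cohort generator with planted ground truth.

The generator emits the seven CSV tables the loader understands, with
pressure-injury trajectories planted per stay from a discrete pattern
mixture.  Each pattern discriminates at least one decision dimension of the
HAPI definitions:

``new_s2plus``           no admission PI, new stage >= 2 after the window —
                         a case under every staging definition.
``stage1_only``          new stage 1 only, past 48 h — separates minimum
                         stage 1 (CANTRIP) from 2.
``admission_dti_worse``  DTI inside 24 h then unstageable later — exercises
                         the asymmetric DTI/unstageable encodings.
``unstageable_staged``   unstageable inside 24 h, numeric stage later — an
                         admission-unstageable PI that is later staged.
``improving_dti``        DTI at admission and at discharge — improvement,
                         excluded only when deterioration is required.
``note_only``            keyword mention in a note, no staging events —
                         separates keyword from staging-only definitions.
``icd_only``             a PI ICD-9 code and nothing else.
``admission_pi``         numeric stage inside 24 h, nothing later —
                         present-on-admission exclusion.
``none``                 no PI.

Source-emission probabilities decouple a stay's true trajectory from what
each source documents, which is how incongruence between chart events,
notes, diagnosis codes and procedure codes is dialed in.  Ground-truth
bookkeeping records the planted pattern and the per-source evidence that
was actually emitted; notes are template text over a PI-free filler
vocabulary — sufficient for lexicon/negation logic and bag-of-words
separability, not realistic clinical language.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ehr_model import CohortStore, load_cohort
from .pi_text import KeywordLexicon

EPOCH = datetime(2130, 1, 1)  # MIMIC-style future-shifted calendar

CASE_PATTERNS = ("new_s2plus", "unstageable_staged", "admission_dti_worse", "note_only")
NONCASE_PI_PATTERNS = ("stage1_only", "improving_dti", "icd_only", "admission_pi")
ALL_PATTERNS = CASE_PATTERNS + NONCASE_PI_PATTERNS + ("none",)

#: VALUE strings charted for each stage token (default stage-item map parses
#: them); item id 551 is the CareVue-style PI stage item.
STAGE_VALUES = {
    "S1": "Stage 1", "S2": "Stage 2", "S3": "Stage 3", "S4": "Stage 4",
    "DTI": "Deep Tissue Injury", "UNSTAGEABLE": "Unable to Stage",
}
STAGE_ITEM_ID = "551"

PI_ICD9_CODE = "70703"
PI_PROCEDURE_CODE = "8622"

_FILLER_VOCAB = (
    "patient stable overnight vitals monitored medication administered "
    "respiratory status unchanged ambulating with assistance tolerating diet "
    "family updated plan continue current regimen pain controlled afebrile "
    "lungs clear abdomen soft neuro intact labs reviewed fluids running "
    "telemetry unremarkable repositioned turned q2h skin intact elsewhere"
).split()


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic cohort.

    Defaults emulate an adult ICU population: mean age 65 (SD 16) years,
    ~10% in-hospital mortality, log-normal stay durations with a median of
    five days, PI onset mostly in the first week, and a 7% target fraction
    of case-generating trajectories.  ``source_emission_probs`` control how
    often a true PI actually shows up in each source (chart events most
    reliable, procedure codes rare and unspecific).
    """

    n_stays: int = 500
    seed: int = 0
    target_prevalence: float = 0.07
    death_rate: float = 0.10
    age_mean: float = 65.0
    age_sd: float = 16.0
    age_min: float = 16.0
    age_max: float = 89.0
    #: log-normal stay duration (hours): median exp(mu), shape sigma
    stay_duration_mu: float = float(np.log(120.0))
    stay_duration_sigma: float = 0.5
    #: PI onset: cutoff + exponential tail (hours past 24 h)
    pi_onset_mean_hours: float = 72.0
    stage_trajectory_probs: dict = field(default_factory=dict)
    source_emission_probs: dict = field(default_factory=lambda: {
        "chart": 1.0, "note": 0.8, "icd9": 0.4, "procedure": 0.05,
    })
    negated_mention_rate: float = 0.10
    date_only_note_rate: float = 0.05
    #: optional token planted in every note of true-PI stays (separability
    #: experiments); must not be a lexicon phrase
    signal_token: Optional[str] = None

    def __post_init__(self):
        if self.n_stays < 1:
            raise ValueError("n_stays must be >= 1")
        for name in ("target_prevalence", "death_rate", "negated_mention_rate",
                     "date_only_note_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for k, v in self.source_emission_probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"source_emission_probs[{k}] must be in [0, 1]")
        if self.target_prevalence > 0.99 and self.death_rate > 0.99:
            raise ValueError(
                "infeasible: prevalence ~1 with death rate ~1 leaves no eligible cases "
                "under definitions that exclude the deceased")

    def trajectory_probs(self) -> dict[str, float]:
        """Pattern mixture; defaults allocate ``target_prevalence`` across
        the case-generating patterns and fixed small mass to the
        discriminating non-case patterns."""
        if self.stage_trajectory_probs:
            probs = dict(self.stage_trajectory_probs)
        else:
            p = self.target_prevalence
            probs = {
                "new_s2plus": 0.70 * p,
                "unstageable_staged": 0.10 * p,
                "admission_dti_worse": 0.05 * p,
                "note_only": 0.15 * p,
                "stage1_only": 0.015,
                "improving_dti": 0.010,
                "icd_only": 0.005,
                "admission_pi": 0.010,
            }
        for pat in probs:
            if pat not in ALL_PATTERNS:
                raise ValueError(f"unknown trajectory pattern {pat!r}")
        rest = 1.0 - sum(probs.values())
        if rest < -1e-9:
            raise ValueError("trajectory pattern probabilities exceed 1")
        probs["none"] = probs.get("none", 0.0) + max(rest, 0.0)
        return probs


def note_text_for(
    pattern: str,
    negated: bool,
    lex: KeywordLexicon,
    rng: np.random.Generator,
    dismissal: bool = False,
    signal_token: Optional[str] = None,
) -> str:
    """Templated note sentence embedding a lexicon phrase (or filler only).

    ``negated`` puts the phrase under a negation trigger; ``dismissal``
    produces a structured "<phrase>: none" line instead.  Filler words come
    from a PI-free vocabulary, so filler-only notes yield zero mentions.
    """
    filler = " ".join(rng.choice(_FILLER_VOCAB, size=8))
    phrase = str(rng.choice(list(lex.phrases)))
    if pattern == "filler":
        body = filler
    elif dismissal:
        body = f"{filler}. {phrase}: none"
    elif negated:
        trigger = str(rng.choice(["no", "without", "no evidence of"]))
        body = f"{filler}. {trigger} {phrase} observed"
    else:
        site = str(rng.choice(["sacral", "heel", "coccyx", "hip"]))
        body = f"{filler}. {site} {phrase} noted on exam"
    if signal_token:
        body = f"{body} {signal_token}"
    return body + "."


@dataclass
class _StayPlan:
    stay_id: str
    pattern: str
    deceased: bool
    age: float
    duration_hours: float
    onset_hours: Optional[float]
    emits: dict


def generate_cohort(
    params: GeneratorParams,
    lex: Optional[KeywordLexicon] = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Emit the seven MIMIC-schema tables and the ground-truth bookkeeping.

    Deterministic given ``params`` (the seed lives inside).  The ground
    truth records, per stay, the planted pattern, demographics, the
    per-source evidence actually emitted and the onset used, from which the
    expected label under any definition can be derived by direct rule
    application.
    """
    if lex is None:
        lex = KeywordLexicon()
    rng = np.random.default_rng(params.seed)
    probs = params.trajectory_probs()
    patterns = list(probs)
    pvec = np.array([probs[p] for p in patterns])
    pvec = pvec / pvec.sum()

    admissions, patients, icustays = [], [], []
    chartevents, noteevents, dx, procs = [], [], [], []
    gt_rows = []
    note_row_id = 1

    for i in range(params.n_stays):
        sid = f"H{i + 1:06d}"
        pid = f"P{i + 1:06d}"
        pattern = str(rng.choice(patterns, p=pvec))
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd),
                            params.age_min, params.age_max))
        duration = float(rng.lognormal(params.stay_duration_mu, params.stay_duration_sigma))
        onset: Optional[float] = None
        if pattern in ("new_s2plus", "unstageable_staged", "admission_dti_worse",
                       "improving_dti", "note_only"):
            onset = 24.0 + 1.0 + float(rng.exponential(params.pi_onset_mean_hours - 24.0))
            duration = max(duration, onset + 12.0)
        elif pattern == "stage1_only":
            onset = 49.0 + float(rng.exponential(params.pi_onset_mean_hours - 24.0))
            duration = max(duration, onset + 12.0)
        duration = max(duration, 36.0)
        deceased = bool(rng.random() < params.death_rate)

        admit = EPOCH + timedelta(days=int(rng.integers(0, 3650)),
                                  hours=float(rng.uniform(0, 24)))
        admit = admit.replace(microsecond=0, second=0)
        disch = admit + timedelta(hours=duration)

        emit = params.source_emission_probs
        emits = {
            "chart": bool(rng.random() < emit.get("chart", 1.0)),
            "note": bool(rng.random() < emit.get("note", 1.0)),
            "icd9": bool(rng.random() < emit.get("icd9", 0.0)),
            "procedure": bool(rng.random() < emit.get("procedure", 0.0)),
        }

        admissions.append({
            "HADM_ID": sid, "SUBJECT_ID": pid,
            "ADMITTIME": admit.strftime("%Y-%m-%d %H:%M:%S"),
            "DISCHTIME": disch.strftime("%Y-%m-%d %H:%M:%S"),
            "DEATHTIME": disch.strftime("%Y-%m-%d %H:%M:%S") if deceased else "",
        })
        dob = admit - timedelta(hours=age * 365.25 * 24.0)
        patients.append({
            "SUBJECT_ID": pid, "DOB": dob.strftime("%Y-%m-%d %H:%M:%S"),
            "DOD": disch.strftime("%Y-%m-%d %H:%M:%S") if deceased else "",
        })
        icustays.append({
            "ICUSTAY_ID": f"I{i + 1:06d}", "HADM_ID": sid,
            "INTIME": (admit + timedelta(hours=1)).strftime("%Y-%m-%d %H:%M:%S"),
            "OUTTIME": (disch - timedelta(hours=1)).strftime("%Y-%m-%d %H:%M:%S"),
        })

        def chart(hours: float, token: str) -> None:
            ts = admit + timedelta(hours=hours)
            chartevents.append({
                "HADM_ID": sid, "CHARTTIME": ts.strftime("%Y-%m-%d %H:%M:%S"),
                "ITEMID": STAGE_ITEM_ID, "VALUE": STAGE_VALUES[token],
            })

        has_pi = pattern != "none"
        signal = params.signal_token if (params.signal_token and pattern in CASE_PATTERNS) else None

        def note(hours: float, kind: str, negated=False, dismissal=False) -> None:
            nonlocal note_row_id
            ts = admit + timedelta(hours=hours)
            date_only = kind == "filler" and rng.random() < params.date_only_note_rate
            noteevents.append({
                "ROW_ID": str(note_row_id), "HADM_ID": sid,
                "CHARTDATE": ts.strftime("%Y-%m-%d"),
                "CHARTTIME": "" if date_only else ts.strftime("%Y-%m-%d %H:%M:%S"),
                "CATEGORY": "Nursing",
                "TEXT": note_text_for(kind, negated, lex, rng,
                                      dismissal=dismissal, signal_token=signal),
            })
            note_row_id += 1

        # baseline filler notes: admission note plus roughly daily notes
        note(2.0, "filler")
        t = 24.0 + float(rng.uniform(-4, 4))
        while t < duration - 2.0:
            note(t, "filler")
            t += 24.0 + float(rng.uniform(-4, 4))
        if rng.random() < params.negated_mention_rate:
            dismiss = bool(rng.random() < 0.3)
            note(float(rng.uniform(4.0, max(8.0, duration - 4.0))), "mention",
                 negated=not dismiss, dismissal=dismiss)

        # planted trajectory
        stage_late = None
        if pattern == "new_s2plus":
            stage_late = str(rng.choice(["S2", "S3", "S4"], p=[0.6, 0.3, 0.1]))
            if emits["chart"]:
                chart(onset, stage_late)
            if emits["note"]:
                note(onset + 0.5, "mention")
        elif pattern == "unstageable_staged":
            stage_late = str(rng.choice(["S2", "S3"]))
            if emits["chart"]:
                chart(float(rng.uniform(2.0, 20.0)), "UNSTAGEABLE")
                chart(onset, stage_late)
            if emits["note"]:
                note(onset + 0.5, "mention")
        elif pattern == "admission_dti_worse":
            if emits["chart"]:
                chart(float(rng.uniform(2.0, 20.0)), "DTI")
                chart(onset, "UNSTAGEABLE")
            if emits["note"]:
                note(onset + 0.5, "mention")
        elif pattern == "improving_dti":
            if emits["chart"]:
                chart(float(rng.uniform(2.0, 20.0)), "DTI")
                chart(onset, "DTI")
            # no late mention: the keyword route must not mask improvement
        elif pattern == "stage1_only":
            if emits["chart"]:
                chart(onset, "S1")
        elif pattern == "note_only":
            note(onset, "mention")  # the note IS the evidence; always emitted
        elif pattern == "icd_only":
            pass
        elif pattern == "admission_pi":
            if emits["chart"]:
                chart(float(rng.uniform(2.0, 20.0)), "S2")
            if emits["note"]:
                note(float(rng.uniform(2.0, 20.0)), "mention")

        wrote_icd = has_pi and pattern != "note_only" and (
            emits["icd9"] or pattern == "icd_only")
        if wrote_icd:
            dx.append({"HADM_ID": sid, "SEQ_NUM": 1, "ICD9_CODE": PI_ICD9_CODE})
        dx.append({"HADM_ID": sid, "SEQ_NUM": 2,
                   "ICD9_CODE": str(rng.choice(["4019", "42731", "5849", "2724"]))})
        wrote_proc = has_pi and emits["procedure"]
        if wrote_proc:
            procs.append({"HADM_ID": sid, "ICD9_CODE": PI_PROCEDURE_CODE})

        gt_rows.append({
            "stay_id": sid, "pattern": pattern, "deceased": deceased,
            "age": age, "duration_hours": duration,
            "onset_hours": onset if onset is not None else np.nan,
            "late_stage": stage_late or "",
            "emitted_chart": has_pi and pattern not in ("note_only", "icd_only") and emits["chart"],
            "emitted_note": (pattern == "note_only") or (
                has_pi and pattern not in ("icd_only", "improving_dti", "stage1_only")
                and emits["note"]),
            "emitted_icd9": wrote_icd,
            "emitted_procedure": wrote_proc,
        })

    tables = {
        "admissions": pd.DataFrame(admissions),
        "patients": pd.DataFrame(patients),
        "icustays": pd.DataFrame(icustays),
        "chartevents": pd.DataFrame(
            chartevents, columns=["HADM_ID", "CHARTTIME", "ITEMID", "VALUE"]),
        "noteevents": pd.DataFrame(
            noteevents,
            columns=["ROW_ID", "HADM_ID", "CHARTDATE", "CHARTTIME", "CATEGORY", "TEXT"]),
        "diagnoses_icd": pd.DataFrame(dx, columns=["HADM_ID", "SEQ_NUM", "ICD9_CODE"]),
        "procedures_icd": pd.DataFrame(procs, columns=["HADM_ID", "ICD9_CODE"]),
    }
    ground_truth = pd.DataFrame(gt_rows)
    return tables, ground_truth


def write_cohort(tables: dict[str, pd.DataFrame], out_dir: "str | Path") -> dict[str, Path]:
    """Write generated tables to MIMIC-named CSV files."""
    names = {
        "admissions": "ADMISSIONS.csv", "patients": "PATIENTS.csv",
        "icustays": "ICUSTAYS.csv", "chartevents": "CHARTEVENTS.csv",
        "noteevents": "NOTEEVENTS.csv", "diagnoses_icd": "DIAGNOSES_ICD.csv",
        "procedures_icd": "PROCEDURES_ICD.csv",
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, df in tables.items():
        paths[key] = out / names[key]
        df.to_csv(paths[key], index=False)
    return paths


def store_from_tables(tables: dict[str, pd.DataFrame], tmp_dir: Optional[Path] = None) -> CohortStore:
    """Load generated tables into a :class:`CohortStore` (via CSV round-trip
    when a directory is given, else through in-memory buffers)."""
    import io

    buffers = {}
    for key, df in tables.items():
        if key == "icustays":
            continue
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        buffers[key] = buf
    return load_cohort(buffers)


def synthetic_annotations(
    ground_truth: pd.DataFrame,
    disagreement_ids: set,
    n: int,
    seed: int = 0,
) -> dict[str, str]:
    """Stand-in nurse annotations for disagreement stays, synthesised from
    the planted trajectory (a case-generating pattern annotates as case).

    Real annotations are an input file; this helper exists so benchmark
    experiments can run end-to-end on generated cohorts.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(disagreement_ids)
    if not pool:
        return {}
    chosen = rng.choice(pool, size=min(n, len(pool)), replace=False)
    by_id = ground_truth.set_index("stay_id")["pattern"]
    return {
        str(sid): ("case" if by_id[str(sid)] in CASE_PATTERNS else "control")
        for sid in chosen
    }
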