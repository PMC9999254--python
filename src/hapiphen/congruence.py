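"""Set-intersection analytics over PI evidence sources and definitions.

The four EHR sources (chart events, notes, diagnosis codes, procedure
codes) rarely agree on whether a stay involved a pressure injury.  This
module extracts, per stay, the set of sources showing any PI evidence —
deliberately ignoring timing and eligibility, so the analysis runs on all
stays — and tabulates exact UpSet-style combination cardinalities.  The
same machinery summarises the overlap of case sets across HAPI definitions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .definitions import DEFAULT_ICD9_PREFIXES, CohortLabeling
from .ehr_model import CohortStore
from .pi_staging import StageMapEntry, default_stage_item_map, extract_staging_events
from .pi_text import KeywordLexicon, scan_note

SOURCES = ("chart_events", "notes", "diagnosis_codes", "procedure_codes")

#: Default PI-adjacent procedure codes (ICD-9 procedures): excisional /
#: non-excisional debridement of wound.  Procedure codes are not PI-specific;
#: counts for this source are strongly config-dependent.
DEFAULT_PROCEDURE_CODES = ("8322", "8345", "8622", "8628")


@dataclass(frozen=True)
class IndicationSet:
    stay_id: str
    sources: frozenset

    def __post_init__(self):
        if not self.sources:
            raise ValueError("an included stay must have at least one source")
        unknown = set(self.sources) - set(SOURCES)
        if unknown:
            raise ValueError(f"unknown sources {unknown}")


def source_indications(
    store: CohortStore,
    lex: Optional[KeywordLexicon] = None,
    stage_item_map: Optional[Sequence[StageMapEntry]] = None,
    icd9_codes: Sequence[str] = DEFAULT_ICD9_PREFIXES,
    procedure_codes: Sequence[str] = DEFAULT_PROCEDURE_CODES,
) -> list[IndicationSet]:
    """Per-stay PI evidence sets over all stays, timing ignored.

    A stay appears iff at least one source shows PI evidence: any mapped PI
    staging chart event (any token, any time), any non-negated keyword
    mention, any configured ICD-9 diagnosis prefix, or any configured
    procedure code prefix.
    """
    if lex is None:
        lex = KeywordLexicon()
    if stage_item_map is None:
        stage_item_map = default_stage_item_map()
    icd_prefixes = tuple(icd9_codes)
    proc_prefixes = tuple(procedure_codes)

    out: list[IndicationSet] = []
    for sid in sorted(store.stays):
        stay = store.stays[sid]
        sources = set()
        events, _ = extract_staging_events(store.events_for(sid), stay, stage_item_map)
        if events:
            sources.add("chart_events")
        for note in store.notes_for(sid):
            if any(not m.negated for m in scan_note(note, lex)):
                sources.add("notes")
                break
        if any(d.code.startswith(icd_prefixes) for d in store.diagnoses_for(sid)):
            sources.add("diagnosis_codes")
        if any(p.code.startswith(proc_prefixes) for p in store.procedures_for(sid)):
            sources.add("procedure_codes")
        if sources:
            out.append(IndicationSet(sid, frozenset(sources)))
    return out


@dataclass
class UpSetCounts:
    """Exact partition counts over non-empty member combinations."""

    combination_counts: dict  # frozenset -> int
    member_totals: dict       # member -> int

    @property
    def union_size(self) -> int:
        return sum(self.combination_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"combination": "+".join(sorted(combo)), "degree": len(combo), "count": n}
            for combo, n in self.combination_counts.items()
        ]
        df = pd.DataFrame(rows, columns=["combination", "degree", "count"])
        return df.sort_values(["degree", "combination"], ignore_index=True)


def upset_counts(sets: Iterable[IndicationSet]) -> UpSetCounts:
    """UpSet tabulation of source combinations.

    Combination counts are an exact partition: each stay contributes to the
    single combination equal to its full source set, and the counts sum to
    the number of stays with at least one indication.  Per-source totals
    count every stay whose set contains the source.
    """
    combos: Counter = Counter()
    totals: Counter = Counter({s: 0 for s in SOURCES})
    for s in sets:
        combos[s.sources] += 1
        for member in s.sources:
            totals[member] += 1
    return UpSetCounts(dict(combos), dict(totals))


def definition_overlap(labelings: Mapping[str, CohortLabeling]) -> UpSetCounts:
    """Overlap of case sets across definitions (stay universes must match).

    Counts every definition-combination among stays that are a case under at
    least one definition; the all-definitions cell is the consensus case set.
    """
    names = list(labelings)
    universes = {name: set(lab.labels["stay_id"]) for name, lab in labelings.items()}
    base = universes[names[0]]
    for name in names[1:]:
        diff = len(base ^ universes[name])
        if diff:
            raise ValueError(
                f"label tables disagree on the stay universe: {names[0]} vs {name} "
                f"symmetric difference of {diff} stays")

    case_sets = {name: labelings[name].case_ids() for name in names}
    combos: Counter = Counter()
    totals = {name: len(ids) for name, ids in case_sets.items()}
    for sid in set().union(*case_sets.values()) if case_sets else set():
        membership = frozenset(name for name in names if sid in case_sets[name])
        combos[membership] += 1
    return UpSetCounts(dict(combos), totals)


def consensus_ids(labelings: Mapping[str, CohortLabeling], status: str) -> set[str]:
    """Stays labeled ``status`` by every definition (consensus cases/controls)."""
    sets = []
    for lab in labelings.values():
        sets.append(set(lab.labels.loc[lab.labels["status"] == status, "stay_id"]))
    return set.intersection(*sets) if sets else set()


def plot_upset(counts: UpSetCounts, path: str) -> None:
    """Minimal matrix-and-bars rendering of UpSet counts to a PNG/SVG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = counts.to_frame().sort_values("count", ascending=False, ignore_index=True)
    members = sorted(counts.member_totals)
    fig, (ax_bar, ax_mat) = plt.subplots(
        2, 1, figsize=(max(6, 0.5 * len(df)), 5),
        gridspec_kw={"height_ratios": [3, 1]}, sharex=True)
    ax_bar.bar(range(len(df)), df["count"], color="0.25")
    ax_bar.set_ylabel("stays")
    for i, combo in enumerate(df["combination"]):
        present = set(combo.split("+"))
        for j, m in enumerate(members):
            ax_mat.plot(i, j, "o", color="0.1" if m in present else "0.85", ms=8)
    ax_mat.set_yticks(range(len(members)), members)
    ax_mat.set_xticks([])
    ax_mat.set_ylim(-0.5, len(members) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
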