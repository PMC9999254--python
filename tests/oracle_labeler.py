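"""Independent brute-force HAPI labeler used as a test oracle.

A deliberately naive, loop-everything transcription of the labeling
semantics (eight decision dimensions, admission/discharge stage encodings,
keyword and ICD-9 routes) kept separate from the package engine so the two
cannot share a bug.  It re-parses chart values and re-scans note text with
its own plain string matching rather than the package's regex machinery.
"""

from __future__ import annotations

import re


# admission / discharge encodings, written out by hand
ADMISSION_CODE = {"S1": 1, "S2": 2, "S3": 3, "S4": 4, "DTI": 4, "UNSTAGEABLE": 0}
DISCHARGE_CODE = {"S1": 1, "S2": 2, "S3": 3, "S4": 4, "DTI": 3, "UNSTAGEABLE": 5}

VALUE_TO_TOKEN = {
    "stage 1": "S1", "stage 2": "S2", "stage 3": "S3", "stage 4": "S4",
    "deep tissue injury": "DTI", "unable to stage": "UNSTAGEABLE",
}

PHRASES = ["pressure ulcer", "pressure injury", "pressure sore",
           "decubitus ulcer", "decubitus", "bedsore", "bed sore"]
TRIGGERS = ["no", "not", "without", "denies", "negative for", "free of",
            "ruled out", "no evidence of"]
DISMISSALS = [": none", ": neg", ": negative", ": 0", ": denied"]
WINDOW = 5

PI_ITEM_IDS = {"551", "552", "553", "224631", "224965", "224966"}
ICD_PREFIXES = ("7070", "70725")


def parse_staging(chart_events, stay):
    """[(hours, token)] for PI staging items with recognised values."""
    out = []
    for ev in chart_events:
        if str(ev.item_id) not in PI_ITEM_IDS:
            continue
        token = VALUE_TO_TOKEN.get((ev.value_text or "").strip().lower())
        if token is None:
            continue
        hours = (ev.ts - stay.admit_ts).total_seconds() / 3600.0
        if hours < 0:
            continue
        out.append((hours, token))
    return sorted(out)


def _phrase_spans(text_lower):
    spans = []
    taken = [False] * len(text_lower)
    for phrase in sorted(PHRASES, key=len, reverse=True):
        start = 0
        while True:
            i = text_lower.find(phrase, start)
            if i < 0:
                break
            j = i + len(phrase)
            before_ok = i == 0 or not text_lower[i - 1].isalnum()
            after_ok = j >= len(text_lower) or not text_lower[j].isalnum()
            if before_ok and after_ok and not any(taken[i:j]):
                spans.append((i, j))
                for k in range(i, j):
                    taken[k] = True
            start = i + 1
    return sorted(spans)


def _negated(text_lower, start, end):
    tail = re.sub(r"\s+", " ", text_lower[end:])
    if any(tail.startswith(d) for d in DISMISSALS):
        return True
    sent_start = 0
    for k in range(start - 1, -1, -1):
        if text_lower[k] in ".!?\n":
            sent_start = k + 1
            break
    prefix = text_lower[sent_start:start]
    words = re.findall(r"[a-z0-9]+", prefix)
    for trig in TRIGGERS:
        tw = trig.split()
        for pos in range(len(words) - len(tw) + 1):
            if words[pos:pos + len(tw)] == tw:
                tokens_after_trigger = len(words) - (pos + len(tw))
                if tokens_after_trigger + 1 <= WINDOW:
                    return True
    return False


def note_has_positive_mention(text):
    low = (text or "").lower()
    return any(not _negated(low, i, j) for i, j in _phrase_spans(low))


def positive_mention_times(notes, stay, include_date_only=True):
    """Sorted hours of notes containing a non-negated PI mention."""
    times = []
    for n in notes:
        if n.ts is None:
            continue
        if n.date_only and not include_date_only:
            continue
        if note_has_positive_mention(n.text):
            times.append((n.ts - stay.admit_ts).total_seconds() / 3600.0)
    return sorted(times)


def oracle_label(stay, chart_events, notes, dx_codes, definition: str) -> dict:
    """Label one stay under a built-in definition name; returns a dict with
    status / route / event_hours / exclusion_reason."""
    d = definition.lower()
    if d == "ehapi":
        excl_dead, min_age, cutoff, min_stage = True, 15, 24.0, 2
        dti_ok, keywords, worsen, icd, staging = True, True, True, False, True
        kw_cut, kw_date_only = 24.0, True
    elif d == "cantrip":
        excl_dead, min_age, cutoff, min_stage = False, 15, 48.0, 1
        dti_ok, keywords, worsen, icd, staging = True, True, False, False, True
        kw_cut, kw_date_only = 48.0, False
    elif d == "cramer":
        excl_dead, min_age, cutoff, min_stage = False, 18, 24.0, 2
        dti_ok, keywords, worsen, icd, staging = False, False, False, False, True
        kw_cut, kw_date_only = 24.0, True
    elif d == "sotoodeh":
        excl_dead, min_age, cutoff, min_stage = False, 18, None, None
        dti_ok, keywords, worsen, icd, staging = False, True, False, True, False
        kw_cut, kw_date_only = 24.0, True
    else:
        raise ValueError(definition)

    # ---- common inclusion, checked one by one
    if not any((n.text or "").strip() for n in notes):
        return {"status": "excluded", "reason": "no_notes"}
    if stay.discharge_ts <= stay.admit_ts:
        return {"status": "excluded", "reason": "bad_times"}
    if stay.age_at_admission is None:
        return {"status": "excluded", "reason": "missing_age"}
    if stay.age_at_admission < min_age:
        return {"status": "excluded", "reason": "under_age"}

    staged = parse_staging(chart_events, stay)
    if staging:
        for hours, token in staged:
            if token in ("S1", "S2", "S3", "S4") and hours <= cutoff:
                return {"status": "excluded", "reason": "pi_on_admission"}
    if keywords:
        for hours in positive_mention_times(notes, stay):
            if hours <= 24.0:
                return {"status": "excluded", "reason": "pi_on_admission"}
    if excl_dead and stay.died_in_hospital:
        return {"status": "excluded", "reason": "deceased"}

    # ---- routes
    firing = []  # (hours or None, route)
    if staging:
        evs = [(h, t) for h, t in staged if dti_ok or t in ("S1", "S2", "S3", "S4")]
        adm = 0
        for h, t in evs:
            if h <= cutoff:
                adm = max(adm, ADMISSION_CODE[t])
        disch = None
        disch_time = None
        for h, t in evs:
            if h > cutoff and DISCHARGE_CODE[t] >= min_stage:
                if disch_time is None or h > disch_time or (
                        h == disch_time and DISCHARGE_CODE[t] > disch):
                    disch, disch_time = DISCHARGE_CODE[t], h
        fires = disch is not None and disch >= min_stage and (
            disch > adm if worsen else True)
        if fires:
            first = min(h for h, t in evs
                        if h > cutoff and DISCHARGE_CODE[t] >= min_stage)
            firing.append((first, "staging"))
    if keywords:
        qual = [h for h in positive_mention_times(notes, stay,
                                                  include_date_only=kw_date_only)
                if h > kw_cut]
        if qual:
            firing.append((min(qual), "keyword"))
    if icd:
        if any(c.code.startswith(ICD_PREFIXES) for c in dx_codes):
            firing.append((None, "icd9"))

    timed = [(h, r) for h, r in firing if h is not None]
    if timed:
        h, r = min(timed)
        return {"status": "case", "route": r, "event_hours": h}
    if firing:
        return {"status": "case", "route": firing[0][1], "event_hours": None}
    return {"status": "control"}


def oracle_label_cohort(store, definition: str) -> dict:
    """stay_id -> oracle label dict for every stay in a store."""
    out = {}
    for sid, stay in store.stays.items():
        out[sid] = oracle_label(
            stay, store.events_for(sid), store.notes_for(sid),
            store.diagnoses_for(sid), definition)
    return out
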