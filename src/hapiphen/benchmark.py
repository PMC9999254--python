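"""Leakage-safe case-control benchmark for comparing HAPI definitions.

A classifier trained on notes that already describe the pressure injury is
answering the wrong question, so every stay gets an *event timestamp* and
only notes strictly before it ("notes of interest") contribute features:

* stays with timed PI evidence use the earliest staging chart event or
  positive keyword mention later than 24 h after admission;
* stays without evidence get a timestamp sampled from the case population's
  note-duration distribution (best parametric family by Pearson chi-square
  on equal-probability bins), matched to each stay's true note duration by
  rank so the control duration distribution mirrors the case one without
  exceeding what the stay actually contains.

Documents are the concatenated notes of interest with lexicon phrases
scrubbed; features are TF-IDF vectors (gradient boosting) or fixed-length
token-index sequences (the embedding/max-pool network in
:mod:`hapiphen.nn`).  Test sets share consensus cases and the annotated
disagreement stays and differ only in the sampled consensus controls;
training sets are the per-definition remainder with definition-specific
labels.  Metrics are AUPRC and AUROC per test set with a one-sided paired
t-test across sets for definition comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV

from .definitions import CohortLabeling
from .congruence import consensus_ids
from .ehr_model import ClinicalNote, CohortStore
from .nn import OOV_INDEX, PAD_INDEX, EmbeddingMaxPoolClassifier
from .pi_staging import StageMapEntry, default_stage_item_map, extract_staging_events
from .pi_text import KeywordLexicon, scan_note

logger = logging.getLogger(__name__)

EVIDENCE_CUTOFF_HOURS = 24.0

CANDIDATE_FAMILIES = ("expon", "gamma", "lognorm", "weibull_min")


class LeakageError(AssertionError):
    """A document violated the no-future-notes / no-lexicon-phrase contract."""


# ---------------------------------------------------------------------------
# event timestamps


def case_event_timestamps(
    store: CohortStore,
    stay_ids: Iterable[str],
    lex: KeywordLexicon,
    stage_item_map: Optional[Sequence[StageMapEntry]] = None,
    cutoff_hours: float = EVIDENCE_CUTOFF_HOURS,
) -> dict[str, datetime]:
    """Earliest timed PI evidence per stay: min over staging chart events and
    non-negated keyword mentions strictly later than the cutoff.

    Raises for a requested stay with no qualifying timed evidence (an
    inconsistent case label).
    """
    if stage_item_map is None:
        stage_item_map = default_stage_item_map()
    out: dict[str, datetime] = {}
    for sid in stay_ids:
        stay = store.stays[sid]
        candidates: list[datetime] = []
        events, _ = extract_staging_events(store.events_for(sid), stay, stage_item_map)
        for ev in events:
            if ev.hours_from_admission > cutoff_hours:
                candidates.append(stay.admit_ts + timedelta(hours=ev.hours_from_admission))
        for note in store.notes_for(sid):
            if note.ts is None:
                continue
            if stay.hours_from_admission(note.ts) <= cutoff_hours:
                continue
            if any(not m.negated for m in scan_note(note, lex)):
                candidates.append(note.ts)
        if not candidates:
            raise ValueError(f"stay {sid}: labeled case but no timed PI evidence past "
                             f"{cutoff_hours} h")
        out[sid] = min(candidates)
    return out


# ---------------------------------------------------------------------------
# duration distribution fitting


@dataclass(frozen=True)
class DurationModel:
    """Best parametric family for case note durations (hours)."""

    family: str
    params: tuple
    chi_square: float
    bin_edges: tuple
    all_scores: dict = field(default_factory=dict)
    empirical_sample: tuple = ()

    @property
    def is_empirical(self) -> bool:
        return self.family == "empirical"

    def mean(self) -> float:
        if self.is_empirical:
            return float(np.mean(self.empirical_sample))
        return float(getattr(stats, self.family)(*self.params).mean())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.is_empirical:
            return rng.choice(np.asarray(self.empirical_sample), size=n, replace=True)
        dist = getattr(stats, self.family)(*self.params)
        return np.asarray(dist.rvs(size=n, random_state=rng))


def fit_duration_distribution(
    durations: Sequence[float],
    candidates: Sequence[str] = CANDIDATE_FAMILIES,
    n_bins: int = 20,
    min_n: int = 20,
) -> DurationModel:
    """Maximum-likelihood fit of each candidate family, scored by Pearson
    chi-square on equal-probability bins; smallest score wins, ties broken
    by candidate order.

    The default candidate set nests the exponential inside gamma and
    Weibull, so raw score comparison would let an extra shape parameter win
    on binning noise alone.  Selection therefore applies the standard
    nested-model guard: a family is charged the 95% chi-square quantile for
    each fitted parameter beyond the leanest candidate, and the adjusted
    score is minimised.  Families with equally many parameters compare by
    raw score, exactly as stated.

    Durations must be positive hours.  With fewer than ``min_n`` durations
    (or a degenerate constant sample) the model falls back to the empirical
    distribution, flagged via ``family == "empirical"``.
    """
    arr = np.asarray(list(durations), dtype=float)
    if np.any(arr <= 0):
        raise ValueError("durations must be > 0")
    if len(arr) < min_n or np.ptp(arr) == 0.0:
        logger.warning("duration fit: %d durations (min %d) or degenerate sample; "
                       "using empirical fallback", len(arr), min_n)
        return DurationModel("empirical", (), float("nan"), (), {}, tuple(arr))

    n = len(arr)
    q = np.linspace(0.0, 1.0, n_bins + 1)
    fits: dict[str, tuple] = {}   # family -> (params, chi2, edges, n_shape_params)
    scores: dict[str, float] = {}
    for family in candidates:
        dist_cls = getattr(stats, family)
        try:
            params = dist_cls.fit(arr, floc=0)  # durations anchored at 0
            dist = dist_cls(*params)
            edges = dist.ppf(q)
            edges[0], edges[-1] = -np.inf, np.inf
            observed, _ = np.histogram(arr, bins=edges)
            expected = n / n_bins
            chi2 = float(np.sum((observed - expected) ** 2 / expected))
        except Exception:  # family failed to converge on this sample
            logger.warning("duration fit: family %s failed; skipping", family)
            continue
        # fitted parameter count with loc pinned: scale + shape parameters
        k = 1 + len(dist_cls.shapes.split(",")) if dist_cls.shapes else 1
        fits[family] = (tuple(params), chi2, tuple(dist.ppf(q)), k)
        scores[family] = chi2
    if not fits:
        return DurationModel("empirical", (), float("nan"), (), {}, tuple(arr))
    k_min = min(k for _, _, _, k in fits.values())
    best_name, best_adj = None, np.inf
    for family in candidates:
        if family not in fits:
            continue
        params, chi2, edges, k = fits[family]
        adjusted = chi2 + (float(stats.chi2.ppf(0.95, k - k_min)) if k > k_min else 0.0)
        if adjusted < best_adj:
            best_name, best_adj = family, adjusted
    params, chi2, edges, _ = fits[best_name]
    return DurationModel(best_name, params, chi2, edges, scores)


# ---------------------------------------------------------------------------
# control timestamp assignment


def rank_paired_offsets(true_durations: Sequence[float], sampled: Sequence[float]) -> np.ndarray:
    """Offsets for controls sorted by true duration: the k-th smallest sampled
    duration pairs with the k-th smallest true duration, and each control's
    offset is the smaller of its pair.

    Input order follows sorted true durations; returns the offset per
    control in that order.
    """
    true_sorted = np.sort(np.asarray(true_durations, dtype=float))
    samp_sorted = np.sort(np.asarray(sampled, dtype=float))
    if len(true_sorted) != len(samp_sorted):
        raise ValueError("one sampled duration per control is required")
    return np.minimum(true_sorted, samp_sorted)


@dataclass(frozen=True)
class ControlWindow:
    stay_id: str
    earliest_note_ts: datetime
    true_duration_hours: float
    discharge_ts: datetime


def assign_control_timestamps(
    controls: Sequence[ControlWindow],
    model: DurationModel,
    seed: int,
) -> dict[str, datetime]:
    """Sampled, rank-matched event timestamps for stays without PI evidence.

    One duration is drawn per control from the fitted model; sampled and
    true durations pair by rank, each control's offset is the min of its
    pair, and the timestamp is the earliest note plus the offset, capped at
    discharge.
    """
    if not controls:
        return {}
    rng = np.random.default_rng(seed)
    sampled = model.sample(len(controls), rng)
    order = sorted(range(len(controls)),
                   key=lambda i: (controls[i].true_duration_hours, controls[i].stay_id))
    offsets = rank_paired_offsets([controls[i].true_duration_hours for i in order], sampled)
    out: dict[str, datetime] = {}
    for rank, i in enumerate(order):
        c = controls[i]
        ts = c.earliest_note_ts + timedelta(hours=float(offsets[rank]))
        out[c.stay_id] = min(ts, c.discharge_ts)
    return out


def assign_event_timestamps(
    store: CohortStore,
    lex: KeywordLexicon,
    stage_item_map: Optional[Sequence[StageMapEntry]] = None,
    seed: int = 0,
    min_fit_n: int = 20,
) -> tuple[dict[str, datetime], DurationModel]:
    """Event timestamps for every stay with at least one timed note.

    Definition-agnostic on purpose: the four definitions share one feature
    set, so a stay's timestamp depends only on its evidence, not on which
    policy labels it.  Evidence stays use their earliest timed PI evidence;
    the rest are treated as controls and matched to the case note-duration
    distribution.
    """
    if stage_item_map is None:
        stage_item_map = default_stage_item_map()
    evidence_ids = []
    for sid in sorted(store.stays):
        stay = store.stays[sid]
        events, _ = extract_staging_events(store.events_for(sid), stay, stage_item_map)
        has_evidence = any(e.hours_from_admission > EVIDENCE_CUTOFF_HOURS for e in events)
        if not has_evidence:
            for note in store.notes_for(sid):
                if note.ts is None or stay.hours_from_admission(note.ts) <= EVIDENCE_CUTOFF_HOURS:
                    continue
                if any(not m.negated for m in scan_note(note, lex)):
                    has_evidence = True
                    break
        if has_evidence:
            evidence_ids.append(sid)
    ts_map = case_event_timestamps(store, evidence_ids, lex, stage_item_map)

    durations = []
    for sid, ev_ts in ts_map.items():
        notes = [n for n in store.notes_for(sid) if n.ts is not None]
        if notes:
            d = (ev_ts - min(n.ts for n in notes)).total_seconds() / 3600.0
            if d > 0:
                durations.append(d)
    model = fit_duration_distribution(durations, min_n=min_fit_n) if durations else DurationModel(
        "empirical", (), float("nan"), (), {}, (24.0,))

    controls = []
    for sid in sorted(store.stays):
        if sid in ts_map:
            continue
        stay = store.stays[sid]
        note_ts = [n.ts for n in store.notes_for(sid) if n.ts is not None]
        if not note_ts:
            continue  # no timed notes: the stay cannot enter the experiments
        true_dur = (max(note_ts) - min(note_ts)).total_seconds() / 3600.0
        controls.append(ControlWindow(sid, min(note_ts), true_dur, stay.discharge_ts))
    ts_map.update(assign_control_timestamps(controls, model, seed))
    return ts_map, model


# ---------------------------------------------------------------------------
# documents


@dataclass(frozen=True)
class StayDocument:
    stay_id: str
    event_ts: datetime
    text: str
    n_notes: int
    n_scrubbed: int = 0


def build_documents(
    store: CohortStore,
    event_ts_map: Mapping[str, datetime],
    lex: KeywordLexicon,
) -> list[StayDocument]:
    """Concatenated notes-of-interest per stay, lexicon phrases scrubbed.

    Only notes strictly before the stay's event timestamp contribute; stays
    with none are dropped.  Every lexicon phrase occurrence (negated or not)
    is removed from the document and counted, and the no-phrase invariant is
    re-checked afterwards — a surviving phrase raises :class:`LeakageError`.
    """
    pattern = lex.phrase_pattern()
    docs: list[StayDocument] = []
    for sid in sorted(event_ts_map):
        if sid not in store.stays:
            continue
        ev_ts = event_ts_map[sid]
        parts: list[ClinicalNote] = [
            n for n in store.notes_for(sid)
            if n.ts is not None and n.ts < ev_ts and (n.text or "").strip()
        ]
        if not parts:
            continue
        parts.sort(key=lambda n: n.ts)
        raw = "\n".join(n.text for n in parts)
        scrubbed, n_scrubbed = pattern.subn(" ", raw)
        if pattern.search(scrubbed):
            raise LeakageError(f"stay {sid}: lexicon phrase survived scrubbing")
        docs.append(StayDocument(sid, ev_ts, scrubbed, len(parts), n_scrubbed))
    return docs


def assert_leakage_safe(
    docs: Iterable[StayDocument],
    store: CohortStore,
    lex: KeywordLexicon,
) -> None:
    """Hard assertion of the leakage contract, run on every benchmark.

    Every note whose text appears in a document must strictly precede the
    stay's event timestamp, and no lexicon phrase may survive in any
    document.
    """
    pattern = lex.phrase_pattern()
    for doc in docs:
        if pattern.search(doc.text):
            raise LeakageError(f"stay {doc.stay_id}: lexicon phrase present in document")
        for note in store.notes_for(doc.stay_id):
            if note.ts is None or not (note.text or "").strip():
                continue
            if note.ts >= doc.event_ts:
                snippet = note.text.strip()[:40]
                if snippet and snippet in doc.text:
                    raise LeakageError(
                        f"stay {doc.stay_id}: note at/after event timestamp leaked into document")


# ---------------------------------------------------------------------------
# features


def vectorize_tfidf(
    train_texts: Sequence[str],
    vocab_size: int = 5000,
    fitted: Optional[TfidfVectorizer] = None,
):
    """TF-IDF features over the top ``vocab_size`` training vocabulary
    (smoothed idf, L2 normalisation).  Pass the returned vectorizer back in
    to transform a test split with the training vocabulary."""
    if fitted is not None:
        return fitted.transform(train_texts), fitted
    if not len(train_texts):
        raise ValueError("no documents to vectorize")
    vec = TfidfVectorizer(max_features=vocab_size, smooth_idf=True, norm="l2")
    X = vec.fit_transform(train_texts)
    return X, vec


def build_sequence_vocab(train_texts: Sequence[str], vocab_size: int = 5000) -> dict[str, int]:
    """Frequency-ranked token vocabulary; indices 0/1 reserved for pad/OOV."""
    if not len(train_texts):
        raise ValueError("no documents to vectorize")
    from collections import Counter

    counts: Counter = Counter()
    for text in train_texts:
        counts.update(text.lower().split())
    vocab: dict[str, int] = {}
    for i, (tok, _) in enumerate(counts.most_common(max(0, vocab_size - 2))):
        vocab[tok] = i + 2
    return vocab


def vectorize_sequences(
    texts: Sequence[str], vocab: Mapping[str, int], seq_len: int = 800
) -> np.ndarray:
    """Token-index sequences of exactly ``seq_len``: the tail beyond the
    limit is truncated, shorter documents pad with the reserved index, and
    out-of-vocabulary tokens map to the OOV index."""
    X = np.full((len(texts), seq_len), PAD_INDEX, dtype=np.int64)
    for i, text in enumerate(texts):
        toks = text.lower().split()[:seq_len]
        X[i, : len(toks)] = [vocab.get(t, OOV_INDEX) for t in toks]
    return X


# ---------------------------------------------------------------------------
# test-set assembly


@dataclass
class BenchmarkSplit:
    """Shared test sets plus per-definition training labels."""

    test_sets: list  # list of DataFrame(stay_id, label)
    train_by_definition: dict  # name -> DataFrame(stay_id, label)
    consensus_case_ids: set
    annotated_ids: set
    test_pool: set


def construct_test_sets(
    labelings: Mapping[str, CohortLabeling],
    annotations: Mapping[str, str],
    n_sets: int = 10,
    n_controls: int = 100,
    seed: int = 0,
) -> BenchmarkSplit:
    """Assemble the shared test sets and per-definition training sets.

    Each test set contains all consensus cases, all annotated disagreement
    stays (with the annotator's label) and a fresh random subsample of
    ``n_controls`` consensus controls — the control subsample is the only
    part that varies between sets.  Annotations must reference stays on
    which the definitions actually disagree.  Per definition, the training
    set is its eligible stays outside the pooled test stays, labeled by
    that definition.
    """
    consensus_cases = consensus_ids(labelings, "case")
    consensus_controls = consensus_ids(labelings, "control")
    agreed = consensus_cases | consensus_controls
    all_excluded = set.intersection(*[
        set(lab.labels.loc[lab.labels["status"] == "excluded", "stay_id"])
        for lab in labelings.values()
    ]) if labelings else set()

    bad = [sid for sid in annotations if sid in agreed or sid in all_excluded]
    if bad:
        raise ValueError(f"annotations reference non-disagreement stays: {sorted(bad)[:5]}"
                         f" ({len(bad)} total)")
    for sid, lab in annotations.items():
        if lab not in ("case", "control"):
            raise ValueError(f"annotation for {sid} must be 'case' or 'control', got {lab!r}")

    pool = sorted(consensus_controls - set(annotations))
    if n_controls > len(pool):
        raise ValueError(
            f"n_controls={n_controls} exceeds the consensus-control pool ({len(pool)})")

    rng = np.random.default_rng(seed)
    fixed = [(sid, 1) for sid in sorted(consensus_cases)] + [
        (sid, 1 if annotations[sid] == "case" else 0) for sid in sorted(annotations)
    ]
    test_sets = []
    pooled: set[str] = {sid for sid, _ in fixed}
    for _ in range(n_sets):
        sampled = rng.choice(pool, size=n_controls, replace=False)
        rows = fixed + [(sid, 0) for sid in sampled]
        pooled.update(sampled)
        test_sets.append(pd.DataFrame(rows, columns=["stay_id", "label"]))

    train_by_def = {}
    for name, lab in labelings.items():
        df = lab.labels
        eligible = df[df["status"] != "excluded"]
        mask = ~eligible["stay_id"].isin(pooled)
        train = eligible.loc[mask, ["stay_id", "status"]].copy()
        train["label"] = (train["status"] == "case").astype(int)
        train_by_def[name] = train[["stay_id", "label"]].reset_index(drop=True)
    return BenchmarkSplit(test_sets, train_by_def, consensus_cases, set(annotations), pooled)


# ---------------------------------------------------------------------------
# training and evaluation


DEFAULT_GB_GRID = {"n_estimators": [100], "max_depth": [3], "learning_rate": [0.1]}


@dataclass
class EvalResult:
    definition: str
    classifier: str
    auprc: np.ndarray  # one entry per test set
    auroc: np.ndarray
    best_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.auprc = np.asarray(self.auprc, dtype=float)
        self.auroc = np.asarray(self.auroc, dtype=float)
        if len(self.auprc) != len(self.auroc):
            raise ValueError("metric vectors must align with the test sets")
        for v in (self.auprc, self.auroc):
            if np.any((v < -1e-9) | (v > 1 + 1e-9)) or np.isnan(v).any():
                raise ValueError("metrics must lie in [0, 1]")
        self.auprc = np.clip(self.auprc, 0.0, 1.0)
        self.auroc = np.clip(self.auroc, 0.0, 1.0)

    def summary(self) -> dict:
        return {
            "definition": self.definition,
            "classifier": self.classifier,
            "auprc_mean": float(self.auprc.mean()),
            "auprc_sd": float(self.auprc.std(ddof=1)) if len(self.auprc) > 1 else 0.0,
            "auroc_mean": float(self.auroc.mean()),
            "auroc_sd": float(self.auroc.std(ddof=1)) if len(self.auroc) > 1 else 0.0,
            "n_test_sets": int(len(self.auprc)),
        }


def train_evaluate(
    train_docs: Sequence[StayDocument],
    train_labels: Sequence[int],
    test_sets: Sequence[Sequence[tuple[StayDocument, int]]],
    classifier: str = "gradient_boosting",
    cv_folds: int = 5,
    hyper_grid: Optional[dict] = None,
    seed: int = 0,
    definition: str = "",
    vocab_size: int = 5000,
    seq_len: int = 800,
    nn_epochs: int = 12,
) -> EvalResult:
    """Fit one classifier on a training split and score every test set.

    Hyperparameters come from ``cv_folds``-fold cross-validation on the
    training split maximising AUPRC (average precision); the winning
    configuration is refit on the full split.  Features are fit on the
    training split only and reused on the test splits.
    """
    y_train = np.asarray(train_labels, dtype=int)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training labels are single-class; cannot fit a classifier")
    train_texts = [d.text for d in train_docs]

    aup, aur = [], []
    if classifier == "gradient_boosting":
        X_train, vec = vectorize_tfidf(train_texts, vocab_size=vocab_size)
        grid = hyper_grid or DEFAULT_GB_GRID
        base = GradientBoostingClassifier(random_state=seed)
        n_grid = int(np.prod([len(v) for v in grid.values()]))
        if n_grid > 1:
            search = GridSearchCV(base, grid, cv=cv_folds, scoring="average_precision", n_jobs=1)
            search.fit(X_train.toarray(), y_train)
            model, best = search.best_estimator_, search.best_params_
        else:
            best = {k: v[0] for k, v in grid.items()}
            model = GradientBoostingClassifier(random_state=seed, **best)
            model.fit(X_train.toarray(), y_train)
        for ts in test_sets:
            X_t, _ = vectorize_tfidf([d.text for d, _ in ts], fitted=vec)
            y_t = np.asarray([lab for _, lab in ts], dtype=int)
            scores = model.predict_proba(X_t.toarray())[:, 1]
            aup.append(average_precision_score(y_t, scores))
            aur.append(roc_auc_score(y_t, scores))
    elif classifier == "sequential_nn":
        vocab = build_sequence_vocab(train_texts, vocab_size=vocab_size)
        X_train = vectorize_sequences(train_texts, vocab, seq_len=seq_len)
        grid = hyper_grid or {"lr": [1e-2]}
        best = _nn_cv_select(X_train, y_train, grid, cv_folds, seed, len(vocab) + 2, nn_epochs)
        model = EmbeddingMaxPoolClassifier(
            vocab_size=len(vocab) + 2, epochs=nn_epochs, seed=seed, **best)
        model.fit(X_train, y_train)
        for ts in test_sets:
            X_t = vectorize_sequences([d.text for d, _ in ts], vocab, seq_len=seq_len)
            y_t = np.asarray([lab for _, lab in ts], dtype=int)
            scores = model.decision_function(X_t)
            aup.append(average_precision_score(y_t, scores))
            aur.append(roc_auc_score(y_t, scores))
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    return EvalResult(definition, classifier, np.array(aup), np.array(aur), best)


def _nn_cv_select(X, y, grid: dict, cv_folds: int, seed: int, vocab_size: int,
                  epochs: int) -> dict:
    from itertools import product
    from sklearn.model_selection import StratifiedKFold

    keys = list(grid)
    combos = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]
    if len(combos) == 1:
        return combos[0]
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_combo, best_score = combos[0], -np.inf
    for combo in combos:
        scores = []
        for tr, va in skf.split(X, y):
            m = EmbeddingMaxPoolClassifier(vocab_size=vocab_size, epochs=epochs,
                                           seed=seed, **combo)
            m.fit(X[tr], y[tr])
            scores.append(average_precision_score(y[va], m.decision_function(X[va])))
        mean = float(np.mean(scores))
        if mean > best_score:
            best_combo, best_score = combo, mean
    return best_combo


def paired_onesided_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, bool]:
    """One-sided paired t-test p-value for mean(a - b) > 0.

    Returns ``(p, degenerate)``.  Zero-variance differences are degenerate:
    all-zero differences report p = 0.5, constant nonzero differences report
    p = 0 (mean > 0) or 1 (mean < 0).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length (paired by test set)")
    if len(a) < 2:
        raise ValueError("need at least two paired scores")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.5, True
        return (0.0 if d.mean() > 0 else 1.0), True
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p = float(stats.t.sf(t, df=len(d) - 1))
    return p, False


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class BenchmarkResult:
    results: dict  # (definition, classifier) -> EvalResult
    duration_model: DurationModel
    split: BenchmarkSplit
    n_documents: int
    pairwise_p: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary() for r in self.results.values()])


def run_benchmark(
    store: CohortStore,
    labelings: Mapping[str, CohortLabeling],
    annotations: Mapping[str, str],
    lex: Optional[KeywordLexicon] = None,
    stage_item_map: Optional[Sequence[StageMapEntry]] = None,
    classifiers: Sequence[str] = ("gradient_boosting",),
    n_sets: int = 10,
    n_controls: int = 100,
    seed: int = 0,
    hyper_grid: Optional[dict] = None,
    vocab_size: int = 5000,
    seq_len: int = 800,
    nn_epochs: int = 12,
) -> BenchmarkResult:
    """End-to-end benchmark: timestamps, documents, splits, training, metrics.

    The leakage assertion runs unconditionally on every invocation.  The
    reference comparison (one-sided paired t-test of each definition against
    the best-mean alternative) is reported per classifier and metric.
    """
    if lex is None:
        lex = KeywordLexicon()
    ts_map, duration_model = assign_event_timestamps(
        store, lex, stage_item_map=stage_item_map, seed=seed)
    docs = build_documents(store, ts_map, lex)
    assert_leakage_safe(docs, store, lex)
    doc_by_id = {d.stay_id: d for d in docs}

    split = construct_test_sets(labelings, annotations, n_sets=n_sets,
                                n_controls=n_controls, seed=seed)

    results: dict[tuple[str, str], EvalResult] = {}
    for name, lab in labelings.items():
        train_tbl = split.train_by_definition[name]
        train_tbl = train_tbl[train_tbl["stay_id"].isin(doc_by_id)]
        train_docs = [doc_by_id[sid] for sid in train_tbl["stay_id"]]
        y = train_tbl["label"].to_numpy()
        test_sets = []
        for tdf in split.test_sets:
            tdf = tdf[tdf["stay_id"].isin(doc_by_id)]
            test_sets.append([(doc_by_id[sid], int(l))
                              for sid, l in zip(tdf["stay_id"], tdf["label"])])
        for clf in classifiers:
            results[(name, clf)] = train_evaluate(
                train_docs, y, test_sets, classifier=clf, seed=seed,
                definition=name, hyper_grid=hyper_grid, vocab_size=vocab_size,
                seq_len=seq_len, nn_epochs=nn_epochs)

    pairwise: dict[str, dict] = {}
    for clf in classifiers:
        per_def = {n: r for (n, c), r in results.items() if c == clf}
        for metric in ("auprc", "auroc"):
            means = {n: getattr(r, metric).mean() for n, r in per_def.items()}
            ranked = sorted(means, key=means.get, reverse=True)
            if len(ranked) >= 2:
                a, b = ranked[0], ranked[1]
                p, degen = paired_onesided_ttest(
                    getattr(per_def[a], metric), getattr(per_def[b], metric))
                pairwise[f"{clf}:{metric}:{a}_vs_{b}"] = {
                    "p_value": p, "degenerate": degen, "best": a, "second": b}
    return BenchmarkResult(results, duration_model, split, len(docs), pairwise)
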