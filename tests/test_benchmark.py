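"""Benchmark harness: timestamps, duration matching, documents, splits,
classifiers, significance."""

from datetime import timedelta

import numpy as np
import pytest
from scipy import stats

from hapiphen.benchmark import (
    ControlWindow,
    LeakageError,
    assert_leakage_safe,
    assign_control_timestamps,
    build_documents,
    build_sequence_vocab,
    case_event_timestamps,
    construct_test_sets,
    fit_duration_distribution,
    paired_onesided_ttest,
    rank_paired_offsets,
    run_benchmark,
    train_evaluate,
    vectorize_sequences,
    vectorize_tfidf,
)
from hapiphen.definitions import builtin_definitions, get_definition, label_cohort
from hapiphen.nn import OOV_INDEX, PAD_INDEX
from hapiphen.synthetic import synthetic_annotations

from conftest import chart_at, make_stay, note_at, single_stay_store

FILLER = "routine assessment documented, no acute events"


class TestCaseEventTimestamps:
    def test_min_of_staging_and_mention(self, lex):
        stay = make_stay()
        store = single_stay_store(
            stay,
            chart_events=[chart_at(stay, 30, "Stage 2")],
            notes=[note_at(stay, 40, "pressure ulcer noted")])
        ts = case_event_timestamps(store, [stay.stay_id], lex)
        assert stay.hours_from_admission(ts[stay.stay_id]) == pytest.approx(30.0)

    def test_precutoff_staging_ignored(self, lex):
        stay = make_stay()
        store = single_stay_store(
            stay,
            chart_events=[chart_at(stay, 20, "Stage 2")],
            notes=[note_at(stay, 50, "pressure ulcer noted")])
        ts = case_event_timestamps(store, [stay.stay_id], lex)
        assert stay.hours_from_admission(ts[stay.stay_id]) == pytest.approx(50.0)

    def test_no_timed_evidence_raises(self, lex):
        stay = make_stay()
        store = single_stay_store(stay, notes=[note_at(stay, 5, FILLER)])
        with pytest.raises(ValueError, match="no timed PI evidence"):
            case_event_timestamps(store, [stay.stay_id], lex)


class TestDurationFit:
    def test_exponential_recovered_from_exponential_draws(self):
        rng = np.random.default_rng(42)
        durations = rng.exponential(48.0, size=1000)
        model = fit_duration_distribution(durations)
        assert model.family == "expon"
        assert model.mean() == pytest.approx(48.0, rel=0.10)

    def test_single_candidate_forced(self):
        rng = np.random.default_rng(0)
        model = fit_duration_distribution(rng.gamma(3.0, 10.0, size=200),
                                          candidates=("lognorm",))
        assert model.family == "lognorm"

    def test_small_or_degenerate_samples_fall_back_to_empirical(self):
        model = fit_duration_distribution([5.0] * 50)
        assert model.is_empirical
        few = fit_duration_distribution([1.0, 2.0, 3.0])
        assert few.is_empirical
        draws = few.sample(100, np.random.default_rng(1))
        assert set(np.unique(draws)) <= {1.0, 2.0, 3.0}

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError):
            fit_duration_distribution([1.0, 0.0, 2.0])


class TestRankPairing:
    def test_hand_worked_example(self):
        # true durations 3, 4, 10 days; sampled draws sort to 2, 5, 9:
        # pairs (2,3) (5,4) (9,10) -> offsets 2, 4, 9
        offsets = rank_paired_offsets([3.0, 4.0, 10.0], [9.0, 2.0, 5.0])
        assert offsets.tolist() == [2.0, 4.0, 9.0]

    def test_offset_never_exceeds_true_duration(self):
        rng = np.random.default_rng(3)
        true = np.sort(rng.exponential(100, size=50))
        sampled = rng.exponential(100, size=50)
        offsets = rank_paired_offsets(true, sampled)
        assert np.all(offsets <= true)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_paired_offsets([1.0, 2.0], [1.0])

    def test_discharge_cap_honored_under_adversarial_draws(self):
        stay = make_stay(duration_hours=100.0)
        ctl = ControlWindow(stay.stay_id, stay.admit_ts + timedelta(hours=2),
                            true_duration_hours=96.0, discharge_ts=stay.discharge_ts)

        class HugeModel:
            is_empirical = False

            def sample(self, n, rng):
                return np.full(n, 1e6)

        ts = assign_control_timestamps([ctl], HugeModel(), seed=0)
        assert ts[stay.stay_id] <= stay.discharge_ts

    def test_empty_controls_empty_mapping(self):
        model = fit_duration_distribution([1.0, 2.0])
        assert assign_control_timestamps([], model, seed=0) == {}


class TestDocuments:
    def _store(self):
        stay = make_stay()
        notes = [note_at(stay, 1, "alpha alpha", note_id="n1"),
                 note_at(stay, 10, "beta beta", note_id="n2"),
                 note_at(stay, 30, "gamma gamma", note_id="n3")]
        return stay, single_stay_store(stay, notes=notes)

    def test_only_notes_before_event_contribute(self, lex):
        stay, store = self._store()
        ev_ts = stay.admit_ts + timedelta(hours=20)
        [doc] = build_documents(store, {stay.stay_id: ev_ts}, lex)
        assert "alpha" in doc.text and "beta" in doc.text and "gamma" not in doc.text
        assert doc.n_notes == 2

    def test_stay_with_all_notes_after_event_dropped(self, lex):
        stay, store = self._store()
        ev_ts = stay.admit_ts + timedelta(hours=0.5)
        assert build_documents(store, {stay.stay_id: ev_ts}, lex) == []

    def test_lexicon_phrases_scrubbed_and_counted(self, lex):
        stay = make_stay()
        notes = [note_at(stay, 1, "sacral pressure ulcer and a bedsore noted")]
        store = single_stay_store(stay, notes=notes)
        [doc] = build_documents(store, {stay.stay_id: stay.admit_ts + timedelta(hours=5)}, lex)
        assert doc.n_scrubbed == 2
        assert not lex.phrase_pattern().search(doc.text)
        assert_leakage_safe([doc], store, lex)

    def test_leakage_assertion_catches_future_note(self, lex):
        from hapiphen.benchmark import StayDocument

        stay = make_stay()
        notes = [note_at(stay, 30, "late note unique-content-xyz")]
        store = single_stay_store(stay, notes=notes)
        bad_doc = StayDocument(stay.stay_id, stay.admit_ts + timedelta(hours=5),
                               "late note unique-content-xyz", 1)
        with pytest.raises(LeakageError):
            assert_leakage_safe([bad_doc], store, lex)


class TestVectorize:
    def test_tfidf_shared_word_single_column(self):
        X, vec = vectorize_tfidf(["wound wound", "wound"])
        assert X.shape == (2, 1)
        # idf identical for the only word; rows L2-normalise to 1
        assert np.allclose(np.asarray(X.todense()), [[1.0], [1.0]])

    def test_sequence_truncated_to_length(self):
        text = " ".join(f"w{i}" for i in range(900))
        vocab = build_sequence_vocab([text], vocab_size=2000)
        X = vectorize_sequences([text], vocab, seq_len=800)
        assert X.shape == (1, 800)
        assert np.all(X != PAD_INDEX)

    def test_oov_and_padding(self):
        vocab = build_sequence_vocab(["known words here"], vocab_size=100)
        X = vectorize_sequences(["known unknown"], vocab, seq_len=5)
        assert X[0, 0] == vocab["known"]
        assert X[0, 1] == OOV_INDEX
        assert np.all(X[0, 2:] == PAD_INDEX)

    def test_empty_document_list_rejected(self):
        with pytest.raises(ValueError):
            vectorize_tfidf([])
        with pytest.raises(ValueError):
            build_sequence_vocab([])


@pytest.fixture(scope="module")
def labelings(small_cohort):
    store, _, _ = small_cohort
    return {c.name: label_cohort(store, c) for c in builtin_definitions()}


@pytest.fixture(scope="module")
def bench_inputs(separable_cohort):
    store, gt, _ = separable_cohort
    labs = {name: label_cohort(store, get_definition(name))
            for name in ("ehapi", "cramer")}
    from hapiphen.congruence import consensus_ids
    agreed = consensus_ids(labs, "case") | consensus_ids(labs, "control")
    all_excl = set.intersection(*[
        set(l.labels.loc[l.labels["status"] == "excluded", "stay_id"])
        for l in labs.values()])
    disagreement = set(store.stays) - agreed - all_excl
    ann = synthetic_annotations(gt, disagreement, n=40, seed=1)
    return store, labs, ann


class TestConstructTestSets:
    def test_fixed_parts_shared_controls_differ(self, small_cohort, labelings):
        _, gt, _ = small_cohort
        from hapiphen.congruence import consensus_ids
        agreed = consensus_ids(labelings, "case") | consensus_ids(labelings, "control")
        universe = set(labelings["ehapi"].labels["stay_id"])
        all_excl = set.intersection(*[
            set(l.labels.loc[l.labels["status"] == "excluded", "stay_id"])
            for l in labelings.values()])
        disagreement = universe - agreed - all_excl
        ann = synthetic_annotations(gt, disagreement, n=10, seed=1)
        split = construct_test_sets(labelings, ann, n_sets=3, n_controls=30, seed=2)
        fixed = split.consensus_case_ids | split.annotated_ids
        sets = [set(df["stay_id"]) for df in split.test_sets]
        for s in sets:
            assert fixed <= s
            assert len(s) == len(fixed) + 30
        assert sets[0] != sets[1]  # control subsample varies

    def test_train_test_disjoint_per_definition(self, small_cohort, labelings):
        _, gt, _ = small_cohort
        split = construct_test_sets(labelings, {}, n_sets=2, n_controls=20, seed=0)
        for name, train in split.train_by_definition.items():
            assert not (set(train["stay_id"]) & split.test_pool)
            eligible = set(labelings[name].labels.loc[
                labelings[name].labels["status"] != "excluded", "stay_id"])
            assert set(train["stay_id"]) <= eligible

    def test_annotation_of_consensus_stay_rejected(self, labelings):
        from hapiphen.congruence import consensus_ids
        sid = sorted(consensus_ids(labelings, "control"))[0]
        with pytest.raises(ValueError, match="non-disagreement"):
            construct_test_sets(labelings, {sid: "case"}, n_sets=1, n_controls=5)

    def test_oversized_control_request_rejected(self, labelings):
        with pytest.raises(ValueError, match="exceeds"):
            construct_test_sets(labelings, {}, n_sets=1, n_controls=10 ** 6)

    def test_reproducible_membership(self, labelings):
        a = construct_test_sets(labelings, {}, n_sets=2, n_controls=25, seed=9)
        b = construct_test_sets(labelings, {}, n_sets=2, n_controls=25, seed=9)
        for da, db in zip(a.test_sets, b.test_sets):
            assert da["stay_id"].tolist() == db["stay_id"].tolist()


class TestPairedTTest:
    def test_identical_scores_half(self):
        p, degen = paired_onesided_ttest([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (p, degen) == (0.5, True)

    def test_constant_positive_difference_zero(self):
        p, degen = paired_onesided_ttest([0.6, 0.7, 0.8], [0.5, 0.6, 0.7])
        assert (p, degen) == (0.0, True)

    def test_textbook_hand_computation(self):
        d = np.array([0.02, 0.01, 0.03, 0.02, 0.02])
        a = 0.5 + d
        b = np.full(5, 0.5)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        expected = float(stats.t.sf(t, df=4))
        p, degen = paired_onesided_ttest(a, b)
        assert not degen
        assert p == pytest.approx(expected, rel=1e-12)
        assert p < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_onesided_ttest([0.1, 0.2], [0.1])


class TestTrainEvaluate:
    def _docs(self, n, signal_rate, seed=0):
        """Synthetic documents: cases carry a signal token, controls don't."""
        from hapiphen.benchmark import StayDocument
        from datetime import datetime

        rng = np.random.default_rng(seed)
        vocab = "alpha beta gamma delta epsilon zeta eta theta".split()
        docs, labels = [], []
        for i in range(n):
            y = int(rng.random() < 0.3)
            words = list(rng.choice(vocab, size=20))
            if y and rng.random() < signal_rate:
                words.insert(int(rng.integers(0, 20)), "marker")
            docs.append(StayDocument(f"d{i}", datetime(2130, 1, 1), " ".join(words), 1))
            labels.append(y)
        return docs, labels

    def test_single_class_training_rejected(self):
        docs, _ = self._docs(10, 1.0)
        with pytest.raises(ValueError, match="single-class"):
            train_evaluate(docs, [0] * 10, [], classifier="gradient_boosting")

    @pytest.mark.parametrize("classifier", ["gradient_boosting", "sequential_nn"])
    def test_separable_documents_learned(self, classifier):
        train_docs, train_y = self._docs(200, 1.0, seed=1)
        test_docs, test_y = self._docs(80, 1.0, seed=2)
        res = train_evaluate(train_docs, train_y, [list(zip(test_docs, test_y))],
                             classifier=classifier, seed=0, seq_len=40,
                             nn_epochs=15)
        assert res.auroc[0] > 0.95
        assert np.all((res.auprc >= 0) & (res.auprc <= 1))

    def test_unknown_classifier_rejected(self):
        docs, y = self._docs(20, 1.0)
        with pytest.raises(ValueError, match="unknown classifier"):
            train_evaluate(docs, y, [], classifier="svm")


class TestRunBenchmark:
    def test_end_to_end_on_separable_cohort(self, bench_inputs):
        store, labelings, ann = bench_inputs
        result = run_benchmark(store, labelings, ann, n_sets=3, n_controls=60,
                               seed=0, classifiers=("gradient_boosting",))
        res = result.results[("ehapi", "gradient_boosting")]
        assert len(res.auroc) == 3
        assert res.auroc.mean() > 0.9
        assert result.n_documents > 0
        assert result.pairwise_p  # best-vs-second comparison reported

    def test_deterministic_given_seed(self, bench_inputs):
        store, labelings, ann = bench_inputs
        r1 = run_benchmark(store, labelings, ann, n_sets=2, n_controls=40, seed=5)
        r2 = run_benchmark(store, labelings, ann, n_sets=2, n_controls=40, seed=5)
        a = r1.results[("ehapi", "gradient_boosting")]
        b = r2.results[("ehapi", "gradient_boosting")]
        assert a.auroc.tolist() == b.auroc.tolist()
        assert a.auprc.tolist() == b.auprc.tolist()
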