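"""Classifier: training formulas, bootstrap confidence, determinism."""

import numpy as np
import pytest

from conftest import make_lineage

from ampligauge.errors import ClassifierError
from ampligauge.nbc import (
    ClassificationResult,
    WordModel,
    _word_log_likelihoods,
    classify,
    classify_batch,
    extract_words,
    train,
)
from ampligauge.taxonomy import Rank, TrainingRecord, TrainingSet


def _ts(*records):
    return TrainingSet(tuple(records))


class TestTrain:
    def test_word_prior_with_word_in_both_sequences(self):
        # N=2 sequences, word present in both: P(w) = (2+0.5)/(2+1)
        ts = _ts(
            TrainingRecord("a", "ACGTACGT", make_lineage("G1")),
            TrainingRecord("b", "ACGTACGTT", make_lineage("G2")),
        )
        model = train(ts)
        w = "ACGTACGT"
        prior = (model.doc_freq[w] + 0.5) / (model.n_sequences + 1)
        assert prior == pytest.approx(2.5 / 3)

    def test_absent_word_gets_pseudocount_floor(self):
        ts = _ts(TrainingRecord("a", "ACGTACGT", make_lineage("G1")))
        model = train(ts)
        loglik = _word_log_likelihoods(model, ["TTTTTTTT"])
        # p(w|G) = (0 + 0.5/(N+1)) / (M+1) with N=M=1
        assert np.exp(loglik[0, 0]) == pytest.approx((0.5 / 2) / 2)

    def test_genus_conditional_formula(self):
        ts = _ts(
            TrainingRecord("a", "ACGTACGT", make_lineage("G1")),
            TrainingRecord("b", "ACGTACGTT", make_lineage("G1")),
            TrainingRecord("c", "TTTTTTTT", make_lineage("G2")),
        )
        model = train(ts)
        w = "ACGTACGT"
        prior = (2 + 0.5) / (3 + 1)
        i = model.genus_index("genus__G1")
        loglik = _word_log_likelihoods(model, [w])
        assert np.exp(loglik[i, 0]) == pytest.approx((2 + prior) / (2 + 1))

    def test_single_genus_always_wins_with_full_confidence(self):
        ts = _ts(TrainingRecord("a", "ACGTACGTAC", make_lineage("G1")))
        model = train(ts)
        res = classify("GGGGCCCCGGGG", model, bootstrap_iters=50, seed=0)
        assert res.winning_genus == "genus__G1"
        assert all(conf == 100 for _, _, conf in res.entries)

    def test_sequence_shorter_than_word_size_names_id(self):
        ts = _ts(TrainingRecord("tiny", "ACGT", make_lineage("G1")))
        with pytest.raises(ClassifierError, match="tiny"):
            train(ts)

    def test_missing_genus_is_error(self):
        from ampligauge.taxonomy import normalize_lineage

        lin = normalize_lineage([("Bacteria", Rank.DOMAIN)])
        with pytest.raises(ClassifierError, match="genus"):
            train(_ts(TrainingRecord("a", "ACGTACGT", lin)))


class TestClassify:
    def test_disjoint_word_sets_give_confidence_100(self, two_genus_model):
        model, ts = two_genus_model
        for rec in ts.records:
            res = classify(rec.sequence, model, bootstrap_iters=200, seed=1)
            genus = rec.lineage.name_at(Rank.GENUS)
            assert res.winning_genus == genus
            assert res.confidence_at(Rank.GENUS) == 100

    def test_symmetric_query_matches_enumeration_oracle(self, two_genus_model):
        # 3 distinct words: 2 favour G1, 1 favours G2; subsample size 1, so
        # bootstrap confidence converges to the exact per-word tally 2/3
        model, ts = two_genus_model
        query = ts.records[0].sequence[:9] + "N" + ts.records[1].sequence[:9]
        words = sorted(extract_words(query, 8))
        assert len(words) == 3
        loglik = _word_log_likelihoods(model, words)
        wins = np.argmax(loglik, axis=0)  # oracle: per-word winner
        expected = np.mean(wins == model.genus_index("genus__G1"))
        iters = 10_000
        res = classify(query, model, bootstrap_iters=iters, seed=3)
        se = np.sqrt(expected * (1 - expected) / iters)
        observed = res.genus_trial_counts.get("genus__G1", 0) / iters
        assert abs(observed - expected) <= 3 * se
        # both genera share the family, so family-level confidence is 100
        assert res.confidence_at(Rank.FAMILY) == 100

    def test_single_bootstrap_iteration_gives_binary_confidence(self, two_genus_model):
        model, ts = two_genus_model
        query = ts.records[0].sequence[:9] + "N" + ts.records[1].sequence[:9]
        res = classify(query, model, bootstrap_iters=1, seed=9)
        assert {conf for _, _, conf in res.entries} <= {0, 100}

    def test_parent_confidence_bounds_child_and_tally_sums(self, two_genus_model):
        model, ts = two_genus_model
        query = ts.records[0].sequence[:9] + "N" + ts.records[1].sequence[:9]
        res = classify(query, model, bootstrap_iters=500, seed=4)
        confs = {r: c for r, _, c in res.entries}
        assert confs[Rank.FAMILY] >= confs[Rank.GENUS]
        assert confs[Rank.DOMAIN] >= confs[Rank.FAMILY]
        assert sum(res.genus_trial_counts.values()) == 500

    def test_bit_identical_across_runs_with_same_seed(self, two_genus_model):
        model, ts = two_genus_model
        query = ts.records[0].sequence[:9] + "N" + ts.records[1].sequence[:9]
        a = classify(query, model, bootstrap_iters=300, seed=11)
        b = classify(query, model, bootstrap_iters=300, seed=11)
        assert a == b

    def test_no_valid_words_records_failure(self, two_genus_model):
        model, _ = two_genus_model
        res = classify("NNNNNNNNNN", model, bootstrap_iters=10, seed=0)
        assert res.failed and res.reason == "no valid words"
        assert res.entries == ()


class TestClassifyBatch:
    def test_empty_batch(self, two_genus_model):
        model, _ = two_genus_model
        assert classify_batch([], model) == []

    def test_batch_equals_mapped_single_calls_with_derived_seeds(
        self, two_genus_model
    ):
        from ampligauge.nbc import derive_seed

        model, ts = two_genus_model
        queries = [(f"q{i}", ts.records[i % 2].sequence) for i in range(4)]
        batch = classify_batch(queries, model, bootstrap_iters=100, seed=21)
        for (qid, seq), res in zip(queries, batch):
            single = classify(
                seq, model, bootstrap_iters=100, seed=derive_seed(21, qid), query_id=qid
            )
            assert single == res

    def test_permuted_input_yields_permuted_identical_output(self, two_genus_model):
        model, ts = two_genus_model
        queries = [(f"q{i}", ts.records[i % 2].sequence) for i in range(6)]
        forward = classify_batch(queries, model, bootstrap_iters=100, seed=5)
        backward = classify_batch(queries[::-1], model, bootstrap_iters=100, seed=5)
        assert forward == backward[::-1]


def test_model_json_round_trip(two_genus_model, tmp_path):
    model, _ = two_genus_model
    p = tmp_path / "model.json"
    model.save(p)
    loaded = WordModel.load(p)
    assert loaded.genera == model.genera
    assert loaded.doc_freq == model.doc_freq
    assert loaded.genus_lineages == model.genus_lineages
    res_a = classify("ACGTACGTA", model, bootstrap_iters=50, seed=2)
    res_b = classify("ACGTACGTA", loaded, bootstrap_iters=50, seed=2)
    assert res_a == res_b


def test_u_is_read_as_t():
    assert extract_words("ACGUACGU", 8) == {"ACGTACGT"}
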