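import math

import numpy as np
import pytest

from lsubench.classifiers import (
    NaiveBayesKmerClassifier, apply_confidence_threshold, classify, train,
)
from lsubench.classifiers.base import Assignment
from lsubench.refdb import ReferenceDB, ReferenceRecord
from lsubench.taxonomy import Lineage


def lin(*names):
    return Lineage(tuple(names))


def brute_force_scores(records, query, k=8, exclude_id=None):
    """Independent naive-Bayes enumeration: distinct words, Wang smoothing."""
    def words(seq):
        out = []
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if set(w) <= set("ACGT") and w not in out:
                out.append(w)
        return out

    training = [r for r in records if r.id != exclude_id]
    n = len(training)
    doc_words = {r.id: set(words(r.seq)) for r in training}
    genera = {}
    for r in training:
        genera.setdefault(r.lineage.name_at("genus"), []).append(r.id)
    scores = {}
    qwords = words(query)
    for genus, members in genera.items():
        total = 0.0
        for w in qwords:
            nw = sum(1 for ws in doc_words.values() if w in ws)
            prior = (nw + 0.5) / (n + 1)
            m = sum(1 for rid in members if w in doc_words[rid])
            total += math.log((m + prior) / (len(members) + 1))
        scores[genus] = total
    return scores


def make_db(n_genera=3, seq_len=60, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for g in range(n_genera):
        for s in range(2):
            seq = "".join(rng.choice(list("ACGT"), seq_len))
            records.append(ReferenceRecord(
                f"g{g}s{s}", seq,
                lin("F", "P", "C", "O", "Fa", f"G{g}", f"G{g} sp{s}")))
    return ReferenceDB(records)


class TestTrain:
    def test_single_sequence_word_set(self):
        db = ReferenceDB([ReferenceRecord(
            "r", "AAAAAAAAA", lin("F", "P", "C", "O", "Fa", "G"))])
        model = train(db)
        assert set(model.vocab_) == {"AAAAAAAA"}
        assert model.n_train_ == 1

    def test_counts_match_hand_enumeration(self):
        db = ReferenceDB([
            ReferenceRecord("r1", "AAAAAAAAC", lin("F", "P", "C", "O", "Fa", "G1")),
            ReferenceRecord("r2", "AAAAAAAAG", lin("F", "P", "C", "O", "Fa", "G2")),
        ])
        model = train(db)
        # words: r1 -> {AAAAAAAA, AAAAAAAC}; r2 -> {AAAAAAAA, AAAAAAAG}
        assert model.doc_counts_[model.vocab_["AAAAAAAA"]] == 2
        assert model.counts_[model.vocab_["AAAAAAAC"],
                             model.genus_index_["G1"]] == 1
        assert model.counts_[model.vocab_["AAAAAAAC"],
                             model.genus_index_["G2"]] == 0

    def test_words_with_ambiguous_bases_skipped(self):
        db = ReferenceDB([ReferenceRecord(
            "r", "AAAANAAAA", lin("F", "P", "C", "O", "Fa", "G"))])
        model = train(db)
        assert len(model.vocab_) == 0  # every 8-mer spans the N

    def test_missing_genus_rejected(self):
        db = ReferenceDB([ReferenceRecord("r", "ACGTACGTACGT",
                                          lin("F", "P"))])
        with pytest.raises(ValueError, match="genus"):
            train(db)

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            NaiveBayesKmerClassifier().fit([])


class TestClassify:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_winner_matches_brute_force(self, seed):
        db = make_db(n_genera=3, seed=seed)
        model = train(db)
        rng = np.random.default_rng(seed + 100)
        query = "".join(rng.choice(list("ACGT"), 40))
        expected = brute_force_scores(db.records, query)
        a = model.classify_one(query, n_bootstrap=0, orient=False)
        best = max(expected.values())
        winners = {g for g, s in expected.items()
                   if abs(s - best) < 1e-9}
        assert a.name_at("genus") in winners

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_leave_one_out_matches_brute_force(self, seed):
        db = make_db(n_genera=3, seed=seed)
        model = train(db)
        query = db.records[0].seq
        expected = brute_force_scores(db.records, query,
                                      exclude_id=db.records[0].id)
        a = model.classify_one(query, exclude_id=db.records[0].id,
                               n_bootstrap=0, orient=False)
        best = max(expected.values())
        winners = {g for g, s in expected.items() if abs(s - best) < 1e-9}
        assert a.name_at("genus") in winners

    def test_identical_query_unique_words_full_confidence(self):
        db = ReferenceDB([
            ReferenceRecord("r1", "ACGTACGTACGTACGTACGT",
                            lin("F", "P", "C", "O", "Fa", "G1")),
            ReferenceRecord("r2", "TTTTTTTTGGGGGGGGCCCCCCCC",
                            lin("F", "P", "C", "O", "Fa", "G2")),
        ])
        model = train(db)
        a = model.classify_one(db.records[0].seq,
                               rng=np.random.default_rng(0))
        assert a.name_at("genus") == "G1"
        assert all(c == 1.0 for c in a.confidences)

    def test_short_query_unclassified(self, default_db):
        model = train(default_db)
        a = model.classify_one("ACGTA")
        assert not a.is_classified and "shorter" in a.note

    def test_winner_invariant_to_duplication(self):
        # scoring is over the distinct word set, so repeating the query
        # (N-separated, so no new junction words arise) changes nothing
        db = make_db(seed=9)
        model = train(db)
        # query derived from a training record so genus scores cannot tie
        query = db.records[2].seq[:40]
        a1 = model.classify_one(query, n_bootstrap=0, orient=False)
        a2 = model.classify_one(query + "N" + query, n_bootstrap=0,
                                orient=False)
        assert a1.name_at("genus") == a2.name_at("genus") == "G1"

    def test_confidences_non_increasing_with_depth(self, default_db):
        model = NaiveBayesKmerClassifier(random_state=0).fit(default_db)
        query = default_db.records[3].seq[100:300]
        a = model.classify_one(query, exclude_id=default_db.records[3].id,
                               rng=np.random.default_rng(1))
        assert list(a.confidences) == sorted(a.confidences, reverse=True)


class TestConfidenceThreshold:
    def _assign(self, length, confs):
        names = ("F", "P", "C", "O", "Fa", "G")[: len(confs)]
        return Assignment("q", Lineage(names), tuple(confs),
                          query_length=length)

    def test_short_query_uses_50_percent(self):
        a = self._assign(200, (1.0, 1.0, 0.9, 0.8, 0.7, 0.62))
        out = apply_confidence_threshold(a)
        assert out.name_at("genus") == "G"  # 0.62 >= 0.5

    def test_long_query_uses_80_percent(self):
        a = self._assign(400, (1.0, 1.0, 1.0, 0.95, 0.9, 0.62))
        out = apply_confidence_threshold(a)
        assert out.name_at("genus") is None
        assert out.name_at("family") == "Fa"  # 0.9 >= 0.8

    def test_full_confidence_unchanged(self):
        a = self._assign(100, (1.0,) * 6)
        assert apply_confidence_threshold(a) == a


def test_functional_wrapper_equivalent(default_db):
    model = train(default_db)
    q = default_db.records[0].seq[:150]
    a = classify(q, model, n_bootstrap=0)
    b = model.classify_one(q, n_bootstrap=0)
    assert a.lineage == b.lineage


def test_model_save_load_roundtrip(tmp_path, default_db):
    model = train(default_db)
    path = tmp_path / "model.npz"
    model.save(path)
    restored = NaiveBayesKmerClassifier.load(path)
    q = default_db.records[5].seq[200:400]
    a = model.classify_one(q, exclude_id=default_db.records[5].id,
                           n_bootstrap=0)
    b = restored.classify_one(q, exclude_id=default_db.records[5].id,
                              n_bootstrap=0)
    assert a.lineage == b.lineage
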