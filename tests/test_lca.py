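import numpy as np
import pytest

from lsubench.classifiers import (
    Hit, LcaClassifier, LcaParams, apply_min_support, import_nbc_as_hits,
    lca_assign, local_align, read_hit_table, search,
)
from lsubench.classifiers.base import Assignment
from lsubench.refdb import ReferenceDB, ReferenceRecord
from lsubench.taxonomy import Lineage, Taxonomy


def lin(*names):
    return Lineage(tuple(names))


def sw_oracle(a, b, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Full Smith-Waterman DP with affine gaps, cost(g) = open + extend*g."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_identical_sequences(self):
        seq = "ACGT" * 25
        hit = local_align(seq, seq)
        assert hit.score == 200 and hit.identity == 100.0

    def test_disjoint_alphabets_score_zero(self):
        hit = local_align("A" * 30, "C" * 30)
        assert hit.score == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_full_dp_oracle_on_random_30mers(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 30))
        b = "".join(rng.choice(list("ACGT"), 30))
        assert local_align(a, b).score == pytest.approx(sw_oracle(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")


@pytest.fixture
def lineage_db():
    return ReferenceDB([
        ReferenceRecord("x1", "ACGTACGTACGTACGTACGTACGTACGTACGT" * 3,
                        lin("F", "P", "C", "O", "Fa", "G", "X")),
        ReferenceRecord("y1", "ACGTACGTACGTACGTACGTACGTACGTACGA" * 3,
                        lin("F", "P", "C", "O", "Fa", "G", "Y")),
        ReferenceRecord("z1", "TTGGCCAATTGGCCAATTGGCCAATTGGCCAA" * 3,
                        lin("F", "P", "C", "O2", "Fa2", "H", "Z")),
    ])


class TestSearch:
    def test_complete_search_finds_self_on_top(self, lineage_db):
        q = lineage_db["x1"].seq
        hits = search(q, lineage_db, min_score=10, query_id="q")
        assert hits[0].subject_id == "x1"

    def test_leave_one_out_removes_self(self, lineage_db):
        q = lineage_db["x1"].seq
        hits = search(q, lineage_db, min_score=10, exclude_id="x1")
        assert all(h.subject_id != "x1" for h in hits)

    def test_min_score_filters_everything(self, lineage_db):
        hits = search("ACGTACGTACGT", lineage_db, min_score=1e6)
        assert hits == []

    def test_scores_sorted_descending_with_id_tiebreak(self, lineage_db):
        hits = search(lineage_db["x1"].seq, lineage_db, min_score=0)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)


class TestLcaAssign:
    def setup_method(self):
        self.lineages = {
            "x1": lin("F", "P", "C", "O", "Fa", "G", "X"),
            "y1": lin("F", "P", "C", "O", "Fa", "G", "Y"),
            "z1": lin("F", "P", "C", "O2", "Fa2", "H", "Z"),
        }
        self.tax = Taxonomy.from_lineages(self.lineages.values())

    def assign(self, hits, **kw):
        params = LcaParams(min_score=kw.pop("min_score", 50),
                           top_percent=kw.pop("top_percent", 1.0),
                           winscore=kw.pop("winscore", 0.0))
        return lca_assign(hits, params, self.tax, self.lineages, **kw)

    def test_single_hit_gives_full_lineage(self):
        a = self.assign([Hit("q", "x1", 120, 99)])
        assert a.lineage == self.lineages["x1"]

    def test_same_genus_hits_collapse_to_genus(self):
        hits = [Hit("q", "x1", 120, 99), Hit("q", "y1", 119.5, 98)]
        a = self.assign(hits)
        assert a.lineage.deepest_rank == "genus"
        assert a.name_at("genus") == "G"

    def test_best_below_min_score_unclassified(self):
        a = self.assign([Hit("q", "x1", 45, 90)], min_score=50)
        assert not a.is_classified

    def test_top_percent_excludes_weak_hit(self):
        hits = [Hit("q", "x1", 200, 99), Hit("q", "z1", 150, 80)]
        a = self.assign(hits, top_percent=1.0)
        assert a.lineage == self.lineages["x1"]  # z1 outside the 1% band

    def test_widening_top_percent_never_deepens(self):
        hits = [Hit("q", "x1", 200, 99), Hit("q", "y1", 195, 97),
                Hit("q", "z1", 160, 80)]
        depths = []
        for tp in (0.5, 3.0, 25.0, 100.0):
            a = self.assign(hits, top_percent=tp)
            depths.append(len(a.lineage))
        assert depths == sorted(depths, reverse=True)

    def test_result_is_ancestor_of_every_retained_subject(self):
        hits = [Hit("q", "x1", 200, 99), Hit("q", "z1", 199, 97)]
        a = self.assign(hits, top_percent=100.0)
        for sid in ("x1", "z1"):
            truth = self.lineages[sid]
            assert truth.names[:len(a.lineage)] == a.lineage.names

    def test_winscore_acts_as_hard_floor(self):
        hits = [Hit("q", "x1", 200, 99), Hit("q", "z1", 180, 90)]
        a = self.assign(hits, winscore=190.0, top_percent=100.0)
        assert a.lineage == self.lineages["x1"]

    def test_unknown_subject_rejected(self):
        with pytest.raises(KeyError):
            self.assign([Hit("q", "nope", 100, 90)])


class TestMinSupport:
    def _assigns(self, *lineages):
        return [Assignment(f"q{i}", l) for i, l in enumerate(lineages)]

    def test_min_support_one_is_identity(self):
        batch = self._assigns(lin("F", "P"), lin("F"))
        assert apply_min_support(batch, 1) == batch

    def test_lone_genus_read_raised_to_family(self):
        fam = lin("F", "P", "C", "O", "Fa")
        genus = lin("F", "P", "C", "O", "Fa", "G")
        batch = self._assigns(genus, fam, fam)
        out = apply_min_support(batch, 2)
        assert out[0].lineage == fam  # family now holds 3 reads
        assert out[1].lineage == fam

    def test_unanimous_species_unchanged(self):
        sp = lin("F", "P", "C", "O", "Fa", "G", "S")
        batch = self._assigns(sp, sp, sp)
        assert [a.lineage for a in apply_min_support(batch, 3)] == [sp] * 3


class TestImportNbc:
    def setup_method(self):
        self.tax = Taxonomy.from_lineages([
            lin("F", "P", "C", "O", "Fa", "G"),
            lin("F", "P", "C", "O", "Fa2", "G2"),
        ])

    def test_high_confidence_genus_kept(self):
        a = Assignment("q", lin("F", "P", "C", "O", "Fa", "G"),
                       (1.0, 1.0, 1.0, 0.98, 0.95, 0.9))
        out = import_nbc_as_hits([a], LcaParams(min_score=50), self.tax)
        assert out[0].name_at("genus") == "G"

    def test_low_genus_confidence_collapses_to_family(self):
        a = Assignment("q", lin("F", "P", "C", "O", "Fa", "G"),
                       (1.0, 1.0, 1.0, 0.9, 0.7, 0.4))
        out = import_nbc_as_hits([a], LcaParams(min_score=50), self.tax)
        assert out[0].lineage.deepest_rank == "family"

    def test_taxonomy_mismatch_collapses_to_shared_ancestor(self):
        a = Assignment("q", lin("F", "P", "C", "O", "FaX", "GX"),
                       (1.0,) * 6)
        out = import_nbc_as_hits([a], LcaParams(min_score=50), self.tax)
        assert out[0].lineage.deepest_rank == "order"


def test_read_hit_table_parses_12_columns(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\ts1\t98.5\t100\t1\t0\t1\t100\t5\t104\t1e-50\t185.2\n"
        "# comment\n"
    )
    hits = read_hit_table(path)
    assert hits[0].score == 185.2 and hits[0].identity == 98.5
    assert hits[0].sstart == 5


class TestEstimator:
    def test_identity_check_zero_errors_on_complete_db(self, small_db):
        est = LcaClassifier(min_score="auto").fit(small_db)
        ids = small_db.ids()[:6]
        assigns = est.predict_assignments(
            [small_db[i].seq for i in ids], ids=ids)
        for a in assigns:
            truth = small_db[a.query_id].lineage
            assert a.lineage.names == truth.names[:len(a.lineage)]
            assert a.name_at("genus") == truth.name_at("genus")

    def test_lca_erroneous_not_above_top_hit_only(self, small_db):
        """LCA consensus never errs at genus more than top-hit classification."""
        from lsubench.reads import benchmark_primers, build_mock_communities
        from lsubench.taxonomy import INCORRECT, compare_at_rank

        comms, parents = build_mock_communities(
            small_db, benchmark_primers(), 100, [0.0], seed=2)
        reads = comms[("LR0R", 0.0)]
        est = LcaClassifier(min_score="auto").fit(small_db)
        exclude = [r.parent_id for r in reads]
        lca_assigns = est.predict_assignments(reads, exclude_ids=exclude)
        errs_lca = errs_top = 0
        for read, a in zip(reads, lca_assigns):
            truth = small_db[read.parent_id].lineage
            hits = search(read.seq, small_db, min_score=0,
                          exclude_id=read.parent_id)
            if hits:
                top = small_db[hits[0].subject_id].lineage
                if compare_at_rank(top, truth, "genus") == INCORRECT:
                    errs_top += 1
            if compare_at_rank(a.lineage, truth, "genus") == INCORRECT:
                errs_lca += 1
        assert errs_lca <= errs_top
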