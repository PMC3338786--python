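import itertools

import numpy as np
import pytest

from lsubench.classifiers import (
    HomologQuotas, NjPlacementClassifier, assign_from_tree, build_nj_tree,
    select_homologs,
)
from lsubench.classifiers.nj import HomologSet
from lsubench.refdb import ReferenceDB, ReferenceRecord
from lsubench.taxonomy import Lineage


def lin(*names):
    return Lineage(tuple(names))


def tree_path_lengths(tree):
    """Pairwise tip-to-tip path lengths of an skbio tree."""
    tips = list(tree.tips())
    out = {}
    for a, b in itertools.combinations(tips, 2):
        out[frozenset((a.name, b.name))] = a.distance(b)
    return out


class TestBuildNjTree:
    def test_additive_four_taxon_matrix_reproduced_exactly(self):
        # tree: (A:2,B:3):1,(C:4,D:5) with internal edge 1
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ], dtype=float)
        ids = ["A", "B", "C", "D"]
        tree = build_nj_tree(d, ids)
        paths = tree_path_lengths(tree)
        for (i, a), (j, b) in itertools.combinations(enumerate(ids), 2):
            assert paths[frozenset((a, b))] == pytest.approx(d[i, j])

    def test_three_taxa_closed_form_star(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = build_nj_tree(d, ["A", "B", "C"])
        # star branch lengths: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_ultrametric_topology_matches_single_linkage(self):
        # nested ultrametric distances: ((A,B),C),(D,E) heights 1<2<3<4
        d = np.array([
            [0, 1, 2, 4, 4],
            [1, 0, 2, 4, 4],
            [2, 2, 0, 4, 4],
            [4, 4, 4, 0, 3],
            [4, 4, 4, 3, 0],
        ], dtype=float)
        tree = build_nj_tree(d, list("ABCDE"))
        # clades {A,B}, {A,B,C}, {D,E} must appear as bipartitions
        tip_sets = []
        for node in tree.non_tips():
            tip_sets.append(frozenset(t.name for t in node.tips()))
        all_tips = frozenset("ABCDE")
        splits = {s for ts in tip_sets for s in (ts, all_tips - ts)}
        for clade in (frozenset("AB"), frozenset("ABC"), frozenset("DE")):
            assert clade in splits

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            build_nj_tree(np.zeros((2, 2)), ["A", "B"])

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_additive_trees_up_to_eight_taxa(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        # random additive matrix from a random binary tree via skbio
        import skbio

        ids = [f"t{i}" for i in range(n)]
        # build a random caterpillar with random positive branch lengths
        newick_parts = f"({ids[0]}:{rng.uniform(0.1, 1):.3f},{ids[1]}:{rng.uniform(0.1, 1):.3f})"
        for tid in ids[2:]:
            newick_parts = (f"({newick_parts}:{rng.uniform(0.1, 1):.3f},"
                            f"{tid}:{rng.uniform(0.1, 1):.3f})")
        tree = skbio.TreeNode.read([newick_parts + ";"])
        tips = list(tree.tips())
        d = np.zeros((n, n))
        for a, b in itertools.combinations(range(n), 2):
            d[a, b] = d[b, a] = tips[a].distance(tips[b])
        rebuilt = build_nj_tree(d, [t.name for t in tips])
        paths = tree_path_lengths(rebuilt)
        for a, b in itertools.combinations(range(n), 2):
            key = frozenset((tips[a].name, tips[b].name))
            assert paths[key] == pytest.approx(d[a, b], abs=1e-9)


class TestSelectHomologs:
    @pytest.fixture
    def db(self, default_db):
        return default_db

    def test_identity_threshold_excludes_distant(self, db):
        query = db.records[0].seq
        hs = select_homologs(query, db, min_identity=0.90,
                             exclude_id=db.records[0].id)
        for rec in hs.records:
            assert hs.identities[rec.id] >= 0.90

    def test_low_identity_candidate_excluded(self, db):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 3400))
        hs = select_homologs(junk, db, min_identity=0.90)
        assert len(hs.records) == 0

    def test_exhaustion_takes_all_eligible(self, db):
        query = db.records[0].seq
        relaxed = select_homologs(query, db, min_identity=0.0,
                                  exclude_id=db.records[0].id)
        # quotas (10 genera) cannot be met with <=1 per species before
        # at least 10 records are taken
        genera = {r.lineage.name_at("genus") for r in relaxed.records}
        assert len(genera) >= 10

    def test_species_quota_one_per_species(self, db):
        query = db.records[0].seq
        hs = select_homologs(query, db, min_identity=0.0)
        species = [r.lineage.name_at("species") for r in hs.records]
        assert len(species) == len(set(species))


class TestAssignFromTree:
    def _homologs(self, records, query):
        return HomologSet("q", query, list(records),
                          {r.id: 1.0 for r in records})

    def test_query_sister_to_genus_gets_full_support(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), 400))

        def mutate(seq, k, seed):
            r = np.random.default_rng(seed)
            arr = list(seq)
            for i in r.choice(len(seq), size=k, replace=False):
                arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
            return "".join(arr)

        genus_anc = mutate(base, 40, 7)  # shared genus ancestor
        query = mutate(genus_anc, 4, 1)
        recs = [
            ReferenceRecord("near", mutate(genus_anc, 6, 2),
                            lin("F", "P", "C", "O", "Fa", "G", "G s1")),
            ReferenceRecord("mid", mutate(base, 40, 3),
                            lin("F", "P", "C", "O", "Fa", "G2", "G2 s1")),
            ReferenceRecord("far", mutate(base, 120, 4),
                            lin("F", "P", "C", "O2", "Fa2", "G3", "G3 s1")),
        ]
        a = assign_from_tree(query, self._homologs(recs, query),
                             n_bootstrap=50, rng=np.random.default_rng(0))
        assert a.name_at("genus") == "G"
        assert a.confidence_at("genus") == 1.0

    def test_hand_built_five_leaf_clade(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), 300))

        def mutate(seq, k, seed):
            r = np.random.default_rng(seed)
            arr = list(seq)
            for i in r.choice(len(seq), size=k, replace=False):
                arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
            return "".join(arr)

        # two tight same-genus leaves sharing an ancestor with the query,
        # two distant outgroups
        genus_anc = mutate(base, 30, 7)
        recs = [
            ReferenceRecord("a", mutate(genus_anc, 3, 1),
                            lin("F", "P", "C", "O", "Fa", "G", "G sa")),
            ReferenceRecord("b", mutate(genus_anc, 5, 2),
                            lin("F", "P", "C", "O", "Fa", "G", "G sb")),
            ReferenceRecord("c", mutate(base, 60, 3),
                            lin("F", "P", "C", "O", "Fa2", "H", "H sc")),
            ReferenceRecord("d", mutate(base, 110, 4),
                            lin("F", "P", "C2", "O2", "Fa3", "I", "I sd")),
        ]
        query = mutate(genus_anc, 2, 9)
        a = assign_from_tree(query, self._homologs(recs, query),
                             n_bootstrap=0)
        # smallest enclosing clade = {a, b} -> genus G
        assert a.name_at("genus") == "G"

    def test_support_cutoff_clears_unsupported_ranks(self):
        from lsubench.orchestrator import truncate_by_confidence
        from lsubench.classifiers.base import Assignment

        a = Assignment("q", lin("F", "P", "C", "O", "Fa", "G"),
                       (1.0, 1.0, 0.99, 0.97, 0.96, 0.93))
        out = truncate_by_confidence(a, 0.95)
        assert out.name_at("genus") is None
        assert out.name_at("family") == "Fa"

    def test_too_few_homologs_unclassified(self):
        rec = ReferenceRecord("only", "ACGT" * 50,
                              lin("F", "P", "C", "O", "Fa", "G"))
        a = assign_from_tree("ACGT" * 50, self._homologs([rec], "ACGT" * 50),
                             n_bootstrap=0)
        assert not a.is_classified and "homolog" in a.note

    def test_degenerate_identical_distances_unclassified(self):
        seq = "ACGT" * 60
        recs = [ReferenceRecord(f"r{i}", seq,
                                lin("F", "P", "C", "O", "Fa", f"G{i}"))
                for i in range(4)]
        a = assign_from_tree(seq, self._homologs(recs, seq), n_bootstrap=0)
        assert not a.is_classified and "degenerate" in a.note


class TestCutoffEffectOnRecovery:
    def test_cutoff_never_increases_recovery_or_coverage(self, small_db):
        from lsubench.orchestrator import truncate_by_confidence
        from lsubench.reads import benchmark_primers, build_mock_communities
        from lsubench.evaluation import evaluate

        comms, _ = build_mock_communities(small_db, benchmark_primers(), 200,
                                          [0.0], seed=4)
        reads = comms[("LR0R", 0.0)]
        truths = {r.id: small_db[r.parent_id].lineage for r in reads}
        est = NjPlacementClassifier(n_bootstrap=50, random_state=0).fit(small_db)
        plain = est.predict_assignments(reads,
                                        exclude_ids=[r.parent_id for r in reads])
        cut = [truncate_by_confidence(a, 0.95) for a in plain]
        for rank in ("genus", "family", "order"):
            s_plain = evaluate(plain, truths, ranks=(rank,))
            s_cut = evaluate(cut, truths, ranks=(rank,))
            assert s_cut.metric(rank, "recovery") <= \
                s_plain.metric(rank, "recovery")
            assert s_cut.metric(rank, "coverage") <= \
                s_plain.metric(rank, "coverage")

    def test_long_queries_beat_short_queries_at_genus(self, small_db):
        from lsubench.reads import benchmark_primers, build_mock_communities

        est = NjPlacementClassifier(n_bootstrap=0, random_state=0).fit(small_db)
        comms, parents = build_mock_communities(
            small_db, benchmark_primers(), 100, [0.0], seed=4)
        reads = comms[("LR0R", 0.0)]

        def recovery(batch, ids):
            n_ok = 0
            for a, pid in zip(batch, ids):
                if a.name_at("genus") == small_db[pid].lineage.name_at("genus"):
                    n_ok += 1
            return n_ok / len(ids)

        short = est.predict_assignments(
            reads, exclude_ids=[r.parent_id for r in reads])
        long_q = est.predict_assignments(
            [small_db[p].seq for p in parents], ids=parents,
            exclude_ids=parents)
        assert recovery(long_q, parents) >= recovery(
            short, [r.parent_id for r in reads])


def test_full_data_tree_newick(small_db):
    from lsubench.classifiers.nj import full_data_tree_newick
    import skbio

    query = small_db.records[0].seq
    hs = select_homologs(query, small_db, min_identity=0.0,
                         exclude_id=small_db.records[0].id, query_id="QX")
    nwk = full_data_tree_newick(query, hs)
    tree = skbio.TreeNode.read([nwk])
    assert "QX" in {t.name for t in tree.tips()}
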