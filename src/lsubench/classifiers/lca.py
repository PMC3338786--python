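"""Similarity search with lowest-common-ancestor consensus assignment.

A query is aligned locally (Smith-Waterman, affine gaps) against every
reference; hits surviving a minimum-score filter and a top-percent band
below the best score are collapsed onto the deepest taxon shared by all
their lineages. Heterogeneous hit sets therefore produce inclusive
(higher-rank) assignments rather than wrong specific ones — the behaviour
that gives this method its characteristically low error rate.

Raw Smith-Waterman scores stand in for the bit scores of an external
search engine; the stock thresholds (50 for 50 bp fragments, 100
otherwise) are kept with that caveat. NBC assignments can be imported
and re-parsed with confidence-as-score, and external 12-column tabular
hit files are accepted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import edlib
import numpy as np
from Bio import Align
from sklearn.base import BaseEstimator

from ..orient import orient_query
from ..refdb import ReferenceDB
from ..taxonomy import Lineage, RANKS, Taxonomy, lowest_common_ancestor, rank_index
from .base import Assignment

__all__ = [
    "Hit",
    "LcaParams",
    "LcaClassifier",
    "default_scoring",
    "local_align",
    "search",
    "lca_assign",
    "apply_min_support",
    "import_nbc_as_hits",
    "read_hit_table",
    "min_score_for_length",
]


@dataclass(frozen=True)
class Hit:
    """One scored query-subject alignment."""

    query_id: str
    subject_id: str
    score: float
    identity: float  # percent over the aligned span
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("hit score must be >= 0")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")


@dataclass(frozen=True)
class LcaParams:
    """Consensus parameters: min_support / min_score / top_percent / winscore."""

    min_support: int = 1
    min_score: float = 100.0
    top_percent: float = 1.0
    winscore: float = 0.0

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0.0 <= self.top_percent <= 100.0:
            raise ValueError("top_percent must be in [0, 100]")


def min_score_for_length(length: int) -> float:
    """Stock minimum score: 50 for 50 bp fragments, 100 otherwise."""
    return 50.0 if length <= 50 else 100.0


def default_scoring() -> Align.PairwiseAligner:
    """Local affine-gap aligner: match +2, mismatch -3, gap cost 5 + 2/base."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7   # first gap base pays open (5) + extend (2)
    aligner.extend_gap_score = -2
    return aligner


def local_align(
    query: str,
    subject: str,
    scoring: Optional[Align.PairwiseAligner] = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> Hit:
    """Optimal local alignment of two sequences as a scored Hit.

    Identity is percent matches over the aligned columns (gaps included in
    the denominator). A pair with no positive-scoring local alignment
    returns a score-0 hit with identity 0.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = scoring or default_scoring()
    score = float(aligner.score(query, subject))
    if score <= 0:
        return Hit(query_id, subject_id, 0.0, 0.0)
    aln = next(iter(aligner.align(query, subject)))
    counts = aln.counts()
    span = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / span if span else 0.0
    (qs, qe) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    (ss, se) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    return Hit(query_id, subject_id, score, identity,
               qstart=qs + 1, qend=qe, sstart=ss + 1, send=se)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _approx_identity(query: str, subject: str) -> float:
    """Fast percent-identity proxy from infix edit distance."""
    res = edlib.align(query, subject, mode="HW", task="distance")
    d = res["editDistance"]
    if d < 0:
        return 0.0
    return max(0.0, 100.0 * (len(query) - d) / len(query))


def search(
    query: str,
    db: ReferenceDB,
    min_score: float = 0.0,
    exclude_id: Optional[str] = None,
    scoring: Optional[Align.PairwiseAligner] = None,
    query_id: str = "query",
    prefilter: Optional[Mapping[str, set[str]]] = None,
    prefilter_k: int = 11,
) -> list[Hit]:
    """Score the query against every reference; sorted hits >= min_score.

    ``exclude_id`` removes the query's own record (leave-one-out
    scenario). ``prefilter`` maps record id -> k-mer set; subjects sharing
    no ``prefilter_k``-mer with the query are skipped before the full
    dynamic-programming pass (a seed-and-extend shortcut; every reported
    hit is still scored by full DP).
    """
    aligner = scoring or default_scoring()
    qset = _kmer_set(query.upper(), prefilter_k) if prefilter is not None else None
    hits: list[Hit] = []
    for rec in db:
        if rec.id == exclude_id:
            continue
        if qset is not None:
            subj_kmers = prefilter.get(rec.id)
            if subj_kmers is not None and qset.isdisjoint(subj_kmers):
                continue
        score = float(aligner.score(query, rec.seq))
        if score >= min_score and score > 0:
            hits.append(
                Hit(query_id, rec.id, score, _approx_identity(query, rec.seq))
            )
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def lca_assign(
    hits: Sequence[Hit],
    params: LcaParams,
    taxonomy: Taxonomy,
    lineages: Mapping[str, Lineage],
    query_id: Optional[str] = None,
    query_length: Optional[int] = None,
) -> Assignment:
    """Collapse retained hits onto the lowest common ancestor of their taxa.

    Retention: score >= min_score; if winscore > 0 and any hit reaches it,
    only those; then hits within top_percent of the best score. No
    retained hits -> unclassified.
    """
    qid = query_id or (hits[0].query_id if hits else "query")
    retained = [h for h in hits if h.score >= params.min_score]
    if params.winscore > 0 and any(h.score >= params.winscore for h in retained):
        retained = [h for h in retained if h.score >= params.winscore]
    if retained:
        best = max(h.score for h in retained)
        floor = best * (1.0 - params.top_percent / 100.0)
        retained = [h for h in retained if h.score >= floor]
    if not retained:
        return Assignment(query_id=qid, query_length=query_length,
                          note="no hits retained")
    nodes = []
    for h in retained:
        if h.subject_id not in lineages:
            raise KeyError(f"subject {h.subject_id!r} missing from taxonomy")
        nodes.append(taxonomy.node_for(lineages[h.subject_id]))
    lca = lowest_common_ancestor(nodes)
    return Assignment(query_id=qid, lineage=lca.lineage(),
                      query_length=query_length)


def apply_min_support(
    assignments: Sequence[Assignment],
    min_support: int,
    taxonomy: Optional[Taxonomy] = None,
) -> list[Assignment]:
    """Push reads on under-supported taxa up to the nearest supported ancestor.

    Taxa holding fewer than ``min_support`` reads have those reads moved to
    their parent, accumulating from the most specific rank upward, so each
    read ends on its nearest ancestor whose (accumulated) read count meets
    the support threshold. min_support = 1 is the identity.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support == 1:
        return list(assignments)
    # bucket reads by assigned lineage
    buckets: dict[tuple[str, ...], list[int]] = {}
    for i, a in enumerate(assignments):
        buckets.setdefault(a.lineage.names, []).append(i)
    # deepest first: move whole buckets up until they meet support
    for depth in range(len(RANKS), 0, -1):
        for names in [n for n in list(buckets) if len(n) == depth]:
            members = buckets[names]
            if len(members) < min_support:
                parent = names[:-1]
                buckets.setdefault(parent, []).extend(buckets.pop(names))
    out = list(assignments)
    for names, members in buckets.items():
        for i in members:
            a = out[i]
            if a.lineage.names != names:
                out[i] = Assignment(
                    query_id=a.query_id, lineage=Lineage(names),
                    query_length=a.query_length,
                    note=(a.note + " raised by min-support").strip(),
                )
    return out


def import_nbc_as_hits(
    nbc_assignments: Sequence[Assignment],
    params: LcaParams,
    taxonomy: Taxonomy,
) -> list[Assignment]:
    """Re-parse NBC output with confidence (0-100) as the hit score.

    Each query's candidate taxa are its per-rank calls scored by
    confidence x 100; ranks failing min_score are dropped and the call
    collapses to the deepest surviving rank, then to the deepest ancestor
    shared with the reference taxonomy when the classifier's lineage
    disagrees with it.
    """
    out = []
    for a in nbc_assignments:
        if not a.is_classified or a.confidences is None:
            out.append(Assignment(query_id=a.query_id,
                                  query_length=a.query_length,
                                  note=a.note or "unclassified input"))
            continue
        keep = 0
        for conf in a.confidences:
            if conf * 100.0 < params.min_score:
                break
            keep += 1
        if keep == 0:
            out.append(Assignment(query_id=a.query_id,
                                  query_length=a.query_length,
                                  note="all ranks below min score"))
            continue
        candidate = Lineage(a.lineage.names[:keep])
        node = taxonomy.deepest_shared_node(candidate)
        out.append(Assignment(query_id=a.query_id, lineage=node.lineage(),
                              query_length=a.query_length))
    return out


def read_hit_table(path: Union[str, Path]) -> list[Hit]:
    """Parse 12-column tabular hits (bit score column used as the score)."""
    hits = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 12:
                raise ValueError(f"expected 12 tabular columns, got {len(row)}")
            (qid, sid, ident, length, mism, gaps,
             qs, qe, ss, se, evalue, bits) = row[:12]
            hits.append(Hit(
                query_id=qid, subject_id=sid, score=float(bits),
                identity=float(ident),
                qstart=int(qs), qend=int(qe), sstart=int(ss), send=int(se),
            ))
    return hits


class LcaClassifier(BaseEstimator):
    """Similarity search + LCA consensus as a fitted estimator.

    ``min_score='auto'`` picks 50 for <=50 bp queries and 100 otherwise.
    """

    def __init__(
        self,
        min_score: Union[float, str] = "auto",
        top_percent: float = 1.0,
        winscore: float = 0.0,
        min_support: int = 1,
        prefilter: bool = True,
        prefilter_k: int = 11,
    ):
        self.min_score = min_score
        self.top_percent = top_percent
        self.winscore = winscore
        self.min_support = min_support
        self.prefilter = prefilter
        self.prefilter_k = prefilter_k

    def fit(self, X: ReferenceDB, y=None) -> "LcaClassifier":
        if len(X) == 0:
            raise ValueError("empty reference database")
        self.db_ = X
        self.taxonomy_ = X.taxonomy
        self.lineages_ = {rec.id: rec.lineage for rec in X}
        self.scoring_ = default_scoring()
        self.kmer_sets_ = (
            {rec.id: _kmer_set(rec.seq, self.prefilter_k) for rec in X}
            if self.prefilter else None
        )
        step = max(1, len(X) // 3)
        self._orient_refs = [r.seq for r in X.records[::step][:3]]
        return self

    def _params_for(self, length: int) -> LcaParams:
        ms = (min_score_for_length(length) if self.min_score == "auto"
              else float(self.min_score))
        return LcaParams(min_support=self.min_support, min_score=ms,
                         top_percent=self.top_percent, winscore=self.winscore)

    def predict_assignments(
        self,
        X: Sequence,
        ids: Optional[Sequence[str]] = None,
        exclude_ids: Optional[Sequence[Optional[str]]] = None,
    ) -> list[Assignment]:
        seqs = [x.seq if hasattr(x, "seq") else x for x in X]
        if ids is None:
            ids = [x.id if hasattr(x, "id") else f"q{i}" for i, x in enumerate(X)]
        if exclude_ids is None:
            exclude_ids = [None] * len(seqs)
        out = []
        for seq, qid, ex in zip(seqs, ids, exclude_ids):
            seq, _ = orient_query(seq, self._orient_refs)
            params = self._params_for(len(seq))
            hits = search(
                seq, self.db_, min_score=params.min_score, exclude_id=ex,
                scoring=self.scoring_, query_id=qid,
                prefilter=self.kmer_sets_, prefilter_k=self.prefilter_k,
            )
            out.append(lca_assign(hits, params, self.taxonomy_,
                                  self.lineages_, query_id=qid,
                                  query_length=len(seq)))
        return apply_min_support(out, self.min_support)

    def predict(self, X: Sequence) -> list[str]:
        """Deepest assigned taxon name per query ('' if unclassified)."""
        return [
            (a.lineage.names[-1] if a.is_classified else "")
            for a in self.predict_assignments(X)
        ]
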