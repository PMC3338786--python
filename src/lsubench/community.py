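"""Community profiles, ecological distances, and NMDS ordination.

Assignments are summarized at one rank into taxon -> read-count profiles
(reads assigned above the rank are tracked as "unplaced" so totals
reconcile but are excluded from distances). Profiles are compared with
Bray-Curtis dissimilarity and a simplified taxonomy-based UniFrac — the
fraction of taxonomy-tree edges unique to one community among all edges
present in either, with unit edge lengths — and embedded by non-metric
multidimensional scaling (Kruskal stress-1, monotone regression, best of
several seeded restarts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.manifold import MDS

from .classifiers.base import Assignment
from .taxonomy import Taxonomy, TaxonomyNode, rank_index

__all__ = [
    "CommunityProfile",
    "DistanceMatrix",
    "profile",
    "normalize_sizes",
    "bray_curtis",
    "simple_unifrac",
    "distance_matrix",
    "nmds",
    "pool",
    "write_profiles_tsv",
    "write_distance_tsv",
]


@dataclass
class CommunityProfile:
    """Taxon -> read count at one rank for one dataset."""

    label: str
    rank: str
    counts: dict[str, int] = field(default_factory=dict)
    unplaced: int = 0

    def __post_init__(self) -> None:
        rank_index(self.rank)  # validates
        if any(c < 0 for c in self.counts.values()) or self.unplaced < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        """Placed reads (excludes unplaced)."""
        return sum(self.counts.values())

    def present(self) -> set[str]:
        return {t for t, c in self.counts.items() if c > 0}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with dataset labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "values", v)


def profile(
    assignments: Sequence[Assignment],
    rank: str,
    taxonomy: Optional[Taxonomy] = None,
    label: str = "community",
) -> CommunityProfile:
    """Summarize assignments at a rank.

    A read assigned at or below the rank counts toward its rank-level
    ancestor; reads assigned above the rank (or unclassified) are
    unplaced.
    """
    counts: dict[str, int] = {}
    unplaced = 0
    for a in assignments:
        name = a.lineage.name_at(rank)
        if name is None:
            unplaced += 1
        else:
            counts[name] = counts.get(name, 0) + 1
    return CommunityProfile(label=label, rank=rank, counts=counts,
                            unplaced=unplaced)


def _rescale(counts: dict[str, int], target: int) -> dict[str, int]:
    """Largest-remainder rounding to an exact integer total."""
    total = sum(counts.values())
    raw = {t: c * target / total for t, c in counts.items()}
    floors = {t: int(np.floor(v)) for t, v in raw.items()}
    leftover = target - sum(floors.values())
    order = sorted(raw, key=lambda t: (-(raw[t] - floors[t]), t))
    for t in order[:leftover]:
        floors[t] += 1
    return {t: c for t, c in floors.items() if c > 0}


def normalize_sizes(profiles: Sequence[CommunityProfile]) -> list[CommunityProfile]:
    """Rescale every profile to the minimum placed total across profiles."""
    if not profiles:
        raise ValueError("no profiles to normalize")
    totals = [p.total for p in profiles]
    if any(t == 0 for t in totals):
        raise ValueError("cannot normalize a zero-total profile")
    target = min(totals)
    out = []
    for p in profiles:
        if p.total == target:
            out.append(CommunityProfile(p.label, p.rank, dict(p.counts),
                                        p.unplaced))
        else:
            factor = target / p.total
            out.append(CommunityProfile(
                p.label, p.rank, _rescale(p.counts, target),
                int(round(p.unplaced * factor)),
            ))
    return out


def bray_curtis(p: CommunityProfile, q: CommunityProfile) -> float:
    """Sum |p_t - q_t| / sum (p_t + q_t) over the union of taxa."""
    if p.rank != q.rank:
        raise ValueError("profiles must be at the same rank")
    taxa = set(p.counts) | set(q.counts)
    if not taxa or (p.total == 0 and q.total == 0):
        raise ValueError("cannot compare two empty profiles")
    num = sum(abs(p.counts.get(t, 0) - q.counts.get(t, 0)) for t in taxa)
    den = sum(p.counts.get(t, 0) + q.counts.get(t, 0) for t in taxa)
    return num / den


def _path_edges(taxonomy: Taxonomy, name: str, rank: str) -> frozenset[int]:
    node = taxonomy.find(name, rank)
    if node is None:
        raise KeyError(f"taxon {name!r} at rank {rank!r} not in taxonomy")
    return frozenset(id(n) for n in node.path_from_root()[1:])


def simple_unifrac(
    p: CommunityProfile, q: CommunityProfile, taxonomy: Taxonomy
) -> float:
    """Unweighted taxonomy-UniFrac: unique edges / all edges present.

    Edges are the unit-length root-to-taxon path edges of taxa present
    (count > 0) in either profile; the distance is the fraction of those
    edges lying only on paths of taxa private to one community.
    """
    if p.rank != q.rank:
        raise ValueError("profiles must be at the same rank")
    pres_p, pres_q = p.present(), q.present()
    if not pres_p and not pres_q:
        raise ValueError("cannot compare two empty profiles")
    edges_p = [_path_edges(taxonomy, t, p.rank) for t in pres_p]
    edges_q = [_path_edges(taxonomy, t, q.rank) for t in pres_q]
    union: set[int] = set().union(*edges_p, *edges_q)
    shared_taxa = pres_p & pres_q
    shared_edges: set[int] = set()
    for t in shared_taxa:
        shared_edges |= _path_edges(taxonomy, t, p.rank)
    unique: set[int] = set()
    for t, e in zip(list(pres_p) + list(pres_q), edges_p + edges_q):
        if t not in shared_taxa:
            unique |= e
    unique -= shared_edges
    return len(unique) / len(union)


def distance_matrix(
    profiles: Sequence[CommunityProfile],
    metric: str = "bray_curtis",
    taxonomy: Optional[Taxonomy] = None,
) -> DistanceMatrix:
    """All-pairs profile distances ('bray_curtis' or 'unifrac')."""
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "bray_curtis":
                val = bray_curtis(profiles[i], profiles[j])
            elif metric == "unifrac":
                if taxonomy is None:
                    raise ValueError("unifrac needs a taxonomy")
                val = simple_unifrac(profiles[i], profiles[j], taxonomy)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = val
    return DistanceMatrix(tuple(p.label for p in profiles), d)


def nmds(
    d: DistanceMatrix,
    dims: int = 2,
    restarts: int = 10,
    random_state: Optional[int] = None,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Non-metric MDS: centered coordinates and Kruskal stress-1.

    Monotone-regression SMACOF run to convergence from ``restarts``
    seeded random starts; the best (lowest-stress) embedding is kept.
    """
    n = len(d.labels)
    if np.all(d.values == 0):
        # indistinguishable items embed at a single point
        return np.zeros((n, dims)), 0.0
    if n == 2:
        dist = float(d.values[0, 1])
        coords = np.array([[-dist / 2.0] + [0.0] * (dims - 1),
                           [dist / 2.0] + [0.0] * (dims - 1)])
        return coords, 0.0
    if n < 2:
        raise ValueError("need at least 2 items to ordinate")
    model = MDS(
        n_components=dims,
        metric=False,
        dissimilarity="precomputed",
        n_init=restarts,
        max_iter=max_iter,
        eps=1e-12,
        random_state=random_state,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(d.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return coords, float(model.stress_)


def write_profiles_tsv(profiles: Sequence[CommunityProfile], path) -> None:
    """Long-format TSV: dataset label, rank, taxon, count (+unplaced row)."""
    with open(path, "w") as fh:
        fh.write("label\trank\ttaxon\tcount\n")
        for p in profiles:
            for taxon in sorted(p.counts):
                fh.write(f"{p.label}\t{p.rank}\t{taxon}\t{p.counts[taxon]}\n")
            fh.write(f"{p.label}\t{p.rank}\t__unplaced__\t{p.unplaced}\n")


def write_distance_tsv(d: DistanceMatrix, path) -> None:
    """Square distance matrix as TSV with a label header row/column."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(d.labels) + "\n")
        for label, row in zip(d.labels, d.values):
            fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def pool(profiles: Sequence[CommunityProfile],
         label: Optional[str] = None) -> CommunityProfile:
    """Taxon-wise sum of same-rank profiles; the label records contributors."""
    if not profiles:
        raise ValueError("nothing to pool")
    rank = profiles[0].rank
    if any(p.rank != rank for p in profiles):
        raise ValueError("profiles must share a rank")
    counts: dict[str, int] = {}
    unplaced = 0
    for p in profiles:
        for t, c in p.counts.items():
            counts[t] = counts.get(t, 0) + c
        unplaced += p.unplaced
    return CommunityProfile(
        label=label or "+".join(p.label for p in profiles),
        rank=rank, counts=counts, unplaced=unplaced,
    )
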