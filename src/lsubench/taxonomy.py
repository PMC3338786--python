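"""Rank-structured taxonomic lineages and a rooted taxonomy tree.

The seven-rank backbone (kingdom > phylum > class > order > family >
genus > species) is the frame in which truth comparison, lowest-common-
ancestor consensus, and taxonomy-based community distances all operate.
Intermediate ranks (subphylum, suborder, ...) are deliberately not
modelled: benchmark metrics are only ever reported on the seven canonical
ranks. Name matching is exact and case-sensitive after whitespace
normalization; synonym or anamorph/teleomorph reconciliation is out of
scope (there is no automated way to do it reliably).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "RANKS",
    "RANK_PREFIXES",
    "rank_index",
    "Lineage",
    "TaxonomyNode",
    "Taxonomy",
    "lowest_common_ancestor",
    "compare_at_rank",
    "CORRECT",
    "INCORRECT",
    "UNCLASSIFIED",
]

#: Ordered rank backbone, most inclusive first.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: One-letter prefixes used in the serialized lineage dialect (k__Fungi;p__...).
RANK_PREFIXES: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

CORRECT = "correct"
INCORRECT = "incorrect"
UNCLASSIFIED = "unclassified"


def rank_index(rank: str) -> int:
    """Position of ``rank`` in the backbone (kingdom=0 ... species=6)."""
    try:
        return _RANK_INDEX[rank]
    except KeyError:
        raise ValueError(f"unknown rank: {rank!r}") from None


def _normalize(name: str) -> str:
    return " ".join(name.split())


@dataclass(frozen=True)
class Lineage:
    """Per-rank taxon names forming a contiguous prefix from kingdom down.

    A lineage may stop at any rank (a record identified only to family has
    names for kingdom..family and nothing below). Empty lineages are legal
    and mean "completely unidentified".
    """

    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise ValueError(f"lineage deeper than {len(RANKS)} ranks")
        cleaned = tuple(_normalize(n) for n in self.names)
        if any(not n for n in cleaned):
            raise ValueError("lineage names must be non-empty strings")
        object.__setattr__(self, "names", cleaned)

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    @property
    def depth(self) -> int:
        return len(self.names)

    @property
    def deepest_rank(self) -> Optional[str]:
        return RANKS[len(self.names) - 1] if self.names else None

    def name_at(self, rank: str) -> Optional[str]:
        """Taxon name at ``rank``, or None if the lineage stops above it."""
        i = rank_index(rank)
        return self.names[i] if i < len(self.names) else None

    def has_rank(self, rank: str) -> bool:
        return rank_index(rank) < len(self.names)

    def truncate(self, rank: str) -> "Lineage":
        """Lineage cut down to end at ``rank`` (inclusive)."""
        return Lineage(self.names[: rank_index(rank) + 1])

    # -- serialization -----------------------------------------------------
    def to_string(self) -> str:
        """Semicolon-delimited rank-prefixed form, e.g. ``k__Fungi;p__...``.

        All seven fields are always emitted; absent ranks have empty values,
        so the round trip is lossless.
        """
        fields = []
        for i, prefix in enumerate(RANK_PREFIXES):
            value = self.names[i] if i < len(self.names) else ""
            fields.append(f"{prefix}__{value}")
        return ";".join(fields)

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse the rank-prefixed dialect; trailing empty ranks may be omitted."""
        parts = [p.strip() for p in text.strip().split(";") if p.strip()]
        names: list[str] = []
        for i, part in enumerate(parts):
            if i >= len(RANKS):
                raise ValueError(f"too many ranks in lineage string: {text!r}")
            expected = RANK_PREFIXES[i] + "__"
            if not part.startswith(expected):
                raise ValueError(
                    f"field {i} of {text!r} should start with {expected!r}"
                )
            value = part[len(expected):].strip()
            if not value:
                # absent rank: everything below must be absent too
                for rest in parts[i + 1:]:
                    if rest.split("__", 1)[1].strip():
                        raise ValueError(
                            f"non-contiguous lineage (gap before a named rank): {text!r}"
                        )
                break
            names.append(value)
        return cls(tuple(names))


@dataclass(eq=False)
class TaxonomyNode:
    """One taxon in the rooted tree: (name, rank, parent). Root has rank None."""

    name: str
    rank: Optional[str]
    parent: Optional["TaxonomyNode"] = None
    children: dict[str, "TaxonomyNode"] = field(default_factory=dict)

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def depth(self) -> int:
        # root = 0, kingdom = 1, ... species = 7
        return 0 if self.rank is None else rank_index(self.rank) + 1

    def path_from_root(self) -> list["TaxonomyNode"]:
        path: list[TaxonomyNode] = []
        node: Optional[TaxonomyNode] = self
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def lineage(self) -> Lineage:
        return Lineage(tuple(n.name for n in self.path_from_root()[1:]))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonomyNode({self.rank}:{self.name})"


class Taxonomy:
    """Rooted tree of named taxa over the fixed rank backbone.

    Built incrementally from lineages; each lineage maps to a root-to-node
    path and node names are unique per (rank, parent).
    """

    def __init__(self) -> None:
        self.root = TaxonomyNode(name="root", rank=None)

    def add_lineage(self, lineage: Lineage) -> TaxonomyNode:
        """Insert (or retrieve) the path for ``lineage``; returns its node."""
        node = self.root
        for i, name in enumerate(lineage.names):
            rank = RANKS[i]
            child = node.children.get(name)
            if child is None:
                child = TaxonomyNode(name=name, rank=rank, parent=node)
                node.children[name] = child
            elif child.rank != rank:  # pragma: no cover - defensive
                raise ValueError(f"rank clash at {name!r}")
            node = child
        return node

    def node_for(self, lineage: Lineage) -> TaxonomyNode:
        """Node for ``lineage``; raises KeyError if any step is missing."""
        node = self.root
        for name in lineage.names:
            node = node.children[name]
        return node

    def find(self, name: str, rank: str) -> Optional[TaxonomyNode]:
        """First node called ``name`` at ``rank`` (depth-first), or None."""
        target = rank_index(rank)
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.rank is not None and rank_index(node.rank) == target:
                if node.name == name:
                    return node
                continue  # children are deeper than target
            stack.extend(node.children.values())
        return None

    def deepest_shared_node(self, lineage: Lineage) -> TaxonomyNode:
        """Walk ``lineage`` from the root; stop at the first unknown name."""
        node = self.root
        for name in lineage.names:
            child = node.children.get(name)
            if child is None:
                break
            node = child
        return node

    def iter_nodes(self) -> Iterator[TaxonomyNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children.values())

    @classmethod
    def from_lineages(cls, lineages: Iterable[Lineage]) -> "Taxonomy":
        tax = cls()
        for lin in lineages:
            tax.add_lineage(lin)
        return tax


def lowest_common_ancestor(nodes: Iterable[TaxonomyNode]) -> TaxonomyNode:
    """Deepest node lying on every member's root path.

    The LCA consensus is what turns a heterogeneous set of database hits
    into a single (possibly inclusive) taxonomic call.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("lowest_common_ancestor of an empty set")
    paths = [n.path_from_root() for n in nodes]
    lca = paths[0][0]
    for level in range(min(len(p) for p in paths)):
        first = paths[0][level]
        if all(p[level] is first for p in paths):
            lca = first
        else:
            break
    return lca


def compare_at_rank(predicted: Lineage, truth: Lineage, rank: str) -> str:
    """Score one prediction at one rank: correct / incorrect / unclassified.

    The truth must name the rank (queries whose truth stops above the rank
    are excluded from that rank's denominator by the caller).
    """
    truth_name = truth.name_at(rank)
    if truth_name is None:
        raise ValueError(f"truth lineage has no name at rank {rank!r}")
    predicted_name = predicted.name_at(rank)
    if predicted_name is None:
        return UNCLASSIFIED
    return CORRECT if predicted_name == truth_name else INCORRECT
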