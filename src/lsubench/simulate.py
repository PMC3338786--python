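"""Synthetic LSU-like reference databases with rank-structured divergence.

The generator emulates the statistical structure the benchmark assumes of
a curated rDNA reference set:

* a balanced taxonomy over the seven-rank backbone;
* a mosaic sequence architecture of conserved cores interleaved with
  divergent (expansion) domains — by default twelve divergent domains over
  ~3,400 bp, echoing the classical description of the eukaryote large
  subunit gene;
* sequence divergence that tracks taxonomic rank: a single root sequence
  is evolved down the taxonomy tree, every position mutating independently
  on each branch with its segment's substitution probability scaled by a
  per-rank multiplier, so within-genus identity exceeds between-phylum
  identity by construction;
* exact binding sites for a configurable primer panel embedded in
  conserved anchor segments, mutating at a (very low) primer-footprint
  rate so sites remain findable at <=1 mismatch in almost all records.

Evolution is substitution-only (no indels), which keeps primer
coordinates and fragment arithmetic exact — the clipping and error
analyses downstream are substitution-framed. Rates are stand-ins chosen
for plausible rank cohesion, not estimates of real LSU divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .reads import Primer, benchmark_primers, reverse_complement
from .refdb import ReferenceDB, ReferenceRecord
from .seeding import child_seed
from .taxonomy import RANKS, Lineage, Taxonomy, TaxonomyNode

__all__ = [
    "Segment",
    "DomainArchitecture",
    "default_architecture",
    "PlantedPrimer",
    "default_primer_layout",
    "SimConfig",
    "generate_taxonomy",
    "generate_references",
    "generate_database",
    "degrade_annotations",
    "primer_reference_scaffold",
]


@dataclass(frozen=True)
class Segment:
    """One architecture segment: length, class, per-branch substitution rate."""

    length: int
    kind: str  # "conserved" | "divergent"
    rate: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.kind not in ("conserved", "divergent"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered mosaic of conserved and divergent segments."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("architecture needs at least one segment")
        cons = [s.rate for s in self.segments if s.kind == "conserved"]
        div = [s.rate for s in self.segments if s.kind == "divergent"]
        if cons and div and max(cons) >= min(div):
            raise ValueError(
                "divergent substitution rate must exceed conserved rate"
            )

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def rate_profile(self) -> np.ndarray:
        """Per-position substitution probability (before rank scaling)."""
        return np.concatenate(
            [np.full(s.length, s.rate) for s in self.segments]
        )

    def kind_at(self, pos: int) -> str:
        """Segment class at 1-based position ``pos``."""
        offset = 0
        for s in self.segments:
            offset += s.length
            if pos <= offset:
                return s.kind
        raise IndexError(f"position {pos} beyond architecture ({self.length} bp)")


#: Default per-branch substitution probabilities by segment class.
CONSERVED_RATE = 0.003
DIVERGENT_RATE = 0.025

# (start, end, kind) blueprint, 1-based inclusive: 12 divergent domains
# interleaved with conserved cores over 3,400 bp. Conserved cores at
# 1-80, 601-700, 851-1000, 1151-1250 and 1401-1500 host the benchmark
# primer footprints.
_DEFAULT_BLUEPRINT: tuple[tuple[int, int, str], ...] = (
    (1, 80, "conserved"),
    (81, 280, "divergent"),      # D1
    (281, 380, "conserved"),
    (381, 600, "divergent"),     # D2
    (601, 700, "conserved"),
    (701, 850, "divergent"),     # D3
    (851, 1000, "conserved"),
    (1001, 1150, "divergent"),   # D4
    (1151, 1250, "conserved"),
    (1251, 1400, "divergent"),   # D5
    (1401, 1500, "conserved"),
    (1501, 1650, "divergent"),   # D6
    (1651, 1750, "conserved"),
    (1751, 1900, "divergent"),   # D7
    (1901, 2000, "conserved"),
    (2001, 2150, "divergent"),   # D8
    (2151, 2250, "conserved"),
    (2251, 2400, "divergent"),   # D9
    (2401, 2500, "conserved"),
    (2501, 2650, "divergent"),   # D10
    (2651, 2750, "conserved"),
    (2751, 2900, "divergent"),   # D11
    (2901, 3000, "conserved"),
    (3001, 3150, "divergent"),   # D12
    (3151, 3400, "conserved"),
)


def default_architecture(
    conserved_rate: float = CONSERVED_RATE,
    divergent_rate: float = DIVERGENT_RATE,
) -> DomainArchitecture:
    """The 3,400 bp / 12-divergent-domain default mosaic."""
    segs = []
    for start, end, kind in _DEFAULT_BLUEPRINT:
        rate = conserved_rate if kind == "conserved" else divergent_rate
        segs.append(Segment(end - start + 1, kind, rate))
    return DomainArchitecture(tuple(segs))


@dataclass(frozen=True)
class PlantedPrimer:
    """A primer embedded at a fixed 1-based start in the root sequence."""

    primer: Primer
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.primer) - 1

    def footprint(self) -> str:
        """Plus-strand bases written into the root at start..end."""
        seq = self.primer.seq
        if self.primer.orientation == "reverse":
            seq = reverse_complement(seq)
        # degenerate symbols are concretized to their first expansion
        first = {"R": "A", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "A",
                 "B": "C", "D": "A", "H": "A", "V": "A", "N": "A"}
        return "".join(first.get(c, c) for c in seq)


def default_primer_layout() -> tuple[PlantedPrimer, ...]:
    """Benchmark panel (LR0R, LR3, LR5, LR7) at its published coordinates."""
    planted = []
    for p in benchmark_primers():
        lo = min(p.published_span)
        planted.append(PlantedPrimer(p, lo))
    return tuple(planted)


@dataclass(frozen=True)
class SimConfig:
    """Counts, architecture, primer layout and rates for one synthetic db.

    ``counts`` fixes the balanced taxonomy shape: (phyla, classes per
    phylum, orders per class, families per order, genera per family,
    species per genus, records per species). ``rank_multipliers`` scale
    each segment's substitution probability on branches entering the given
    rank; the trailing value scales the per-record tip branches. The
    defaults give a 64-species database with two lineages at every rank,
    strong between-phylum divergence and tight within-genus cohesion.
    """

    n_phyla: int = 2
    n_classes: int = 2
    n_orders: int = 2
    n_families: int = 2
    n_genera: int = 2
    n_species: int = 2
    n_records: int = 1
    architecture: DomainArchitecture = field(default_factory=default_architecture)
    primer_layout: tuple[PlantedPrimer, ...] = field(
        default_factory=default_primer_layout
    )
    rank_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "kingdom": 1.0,
            "phylum": 3.0,
            "class": 2.0,
            "order": 1.5,
            "family": 1.2,
            "genus": 1.0,
            "species": 0.7,
            "record": 0.3,
        }
    )
    primer_site_rate: float = 0.0002
    kingdom_name: str = "Fungi"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_phyla", "n_classes", "n_orders", "n_families",
                     "n_genera", "n_species", "n_records"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        arch_len = self.architecture.length
        for planted in self.primer_layout:
            if planted.end > arch_len:
                raise ValueError(
                    f"primer {planted.primer.name} at {planted.start} extends "
                    f"beyond the {arch_len} bp architecture"
                )
            for pos in (planted.start, planted.end):
                if self.architecture.kind_at(pos) != "conserved":
                    raise ValueError(
                        f"primer {planted.primer.name} footprint leaves the "
                        "conserved anchor segment"
                    )

    @property
    def species_count(self) -> int:
        return (self.n_phyla * self.n_classes * self.n_orders
                * self.n_families * self.n_genera * self.n_species)


def generate_taxonomy(config: SimConfig) -> Taxonomy:
    """Balanced taxonomy with the configured counts (deterministic)."""
    tax = Taxonomy()
    counts = (config.n_phyla, config.n_classes, config.n_orders,
              config.n_families, config.n_genera, config.n_species)
    prefixes = ("P", "C", "O", "F", "G", "")

    def expand(names: tuple[str, ...], level: int) -> None:
        if level == len(counts):
            tax.add_lineage(Lineage(names))
            return
        for i in range(1, counts[level] + 1):
            if level < 5:
                child = f"{names[-1]}{prefixes[level]}{i}" if level else \
                    f"{prefixes[level]}{i}"
                # include kingdom in path names only implicitly
            else:
                child = f"{names[-1]} sp{i}"
            expand(names + (child,), level + 1)

    expand((config.kingdom_name,), 0)
    return tax


def _mutate(seq: np.ndarray, rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-position substitution: each base i flips with probability rates[i]."""
    out = seq.copy()
    hit = rng.random(seq.size) < rates
    idx = np.flatnonzero(hit)
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = (out[idx] + shift) % 4
    return out


_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return _ALPHABET[arr].tobytes().decode()


def generate_references(taxonomy: Taxonomy, config: SimConfig) -> ReferenceDB:
    """Evolve a root sequence down the taxonomy into a reference database.

    The root is uniform-random ACGT with the primer footprints written in;
    each branch into a rank-r node substitutes every position independently
    with probability segment_rate * rank_multipliers[r] (primer footprints
    use the dedicated low primer_site_rate). Each species leaf emits
    ``n_records`` records on separate tip branches. Deterministic given
    config.seed.
    """
    arch = config.architecture
    rng_root = np.random.default_rng(child_seed(config.seed, "root"))
    root = rng_root.integers(0, 4, size=arch.length, dtype=np.int8)
    base_rates = arch.rate_profile()
    footprint = np.zeros(arch.length, dtype=bool)
    for planted in config.primer_layout:
        fp = planted.footprint()
        root[planted.start - 1: planted.end] = _encode(fp)
        footprint[planted.start - 1: planted.end] = True
    base_rates = np.where(footprint, config.primer_site_rate, base_rates)

    records: list[ReferenceRecord] = []

    def walk(node: TaxonomyNode, seq: np.ndarray) -> None:
        if node.rank == "species":
            mult = config.rank_multipliers.get("record", 0.0)
            species = node.name
            rid_base = "-".join(node.lineage().names[1:]).replace(" ", "-")
            for k in range(1, config.n_records + 1):
                rng = np.random.default_rng(
                    child_seed(config.seed, "tip", species, k)
                )
                tip = _mutate(seq, base_rates * mult, rng)
                records.append(
                    ReferenceRecord(
                        id=f"{rid_base}-r{k}",
                        seq=_decode(tip),
                        lineage=node.lineage(),
                    )
                )
            return
        for name in sorted(node.children):
            child = node.children[name]
            mult = config.rank_multipliers.get(child.rank, 1.0)
            rng = np.random.default_rng(
                child_seed(config.seed, "branch", child.rank, name)
            )
            walk(child, _mutate(seq, base_rates * mult, rng))

    walk(taxonomy.root, root)
    return ReferenceDB(records)


def generate_database(config: SimConfig) -> ReferenceDB:
    """Convenience: taxonomy + references in one call."""
    return generate_references(generate_taxonomy(config), config)


def degrade_annotations(db: ReferenceDB, fraction: float, seed: int = 0) -> ReferenceDB:
    """Truncate a random fraction of lineages, emulating partial annotation.

    Each selected record's lineage is cut to end at a random rank at or
    above genus (i.e. at least the species name is dropped), mirroring the
    incompletely annotated entries found in public nucleotide databases.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for rec in db:
        if fraction > 0 and rng.random() < fraction and len(rec.lineage) > 0:
            cut = int(rng.integers(1, min(len(rec.lineage), 6) + 1))
            out.append(replace(rec, lineage=Lineage(rec.lineage.names[:cut])))
        else:
            out.append(rec)
    return ReferenceDB(out)


def primer_reference_scaffold(length: int = 3396, seed: int = 20120427) -> str:
    """Synthetic stand-in for the yeast 25S rDNA primer coordinate frame.

    Random background with every published LSU primer footprint written at
    its published 1-based coordinate (reverse primers reverse-
    complemented, degenerate symbols concretized). Overlapping primers in
    the published table agree with one another, so the construction is
    consistent; the scaffold reproduces the published coordinate/strand
    semantics without containing any real 25S sequence.
    """
    from .reads import LSU_PRIMERS

    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=length, dtype=np.int8)
    for primer in LSU_PRIMERS:
        lo, hi = sorted(primer.published_span)
        planted = PlantedPrimer(primer, lo)
        fp = planted.footprint()
        existing = _decode(arr[lo - 1: hi])
        arr[lo - 1: hi] = _encode(fp)
    return _decode(arr)
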