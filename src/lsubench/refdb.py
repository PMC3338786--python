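"""Reference sequence databases: loading, filtering, leave-one-out views.

A reference database is an ordered collection of annotated sequences plus
the taxonomy induced by their lineages. Records carry their lineage in the
FASTA description (rank-prefixed ``k__...;p__...`` dialect) so a database
is a single self-contained file; a two-column id -> lineage TSV sidecar is
accepted as an alternate dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import Lineage, Taxonomy

__all__ = [
    "IUPAC_DNA",
    "ReferenceRecord",
    "ReferenceDB",
    "load_references",
    "write_references",
    "filter_dataset",
    "leave_one_out_view",
]

#: Accepted residue alphabet (IUPAC DNA including degeneracies).
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class ReferenceRecord:
    """One database entry: unique id, IUPAC DNA sequence, taxonomic lineage."""

    id: str
    seq: str
    lineage: Lineage = Lineage()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = self.seq.upper()
        if len(seq) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.id}: non-IUPAC symbols {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


class ReferenceDB:
    """Ordered collection of :class:`ReferenceRecord` plus induced taxonomy."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        self.records: list[ReferenceRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id: {rec.id!r}")
            seen.add(rec.id)
        self._by_id = {rec.id: rec for rec in self.records}
        self.taxonomy = Taxonomy.from_lineages(r.lineage for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def __getitem__(self, record_id: str) -> ReferenceRecord:
        return self._by_id[record_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lineage_of(self, record_id: str) -> Lineage:
        return self._by_id[record_id].lineage


def _parse_header_dialect(rec: SeqRecord) -> tuple[str, Lineage]:
    rid = rec.id
    desc = rec.description
    if desc.startswith(rid):
        desc = desc[len(rid):].strip()
    if not desc:
        return rid, Lineage()
    try:
        return rid, Lineage.from_string(desc)
    except ValueError as exc:
        raise ValueError(f"record {rid!r}: unparseable lineage header: {exc}")


def _load_sidecar(path: Union[str, Path]) -> dict[str, Lineage]:
    table: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            table[parts[0]] = Lineage.from_string(parts[1])
    return table


def load_references(
    fasta_path: Union[str, Path],
    annotation_dialect: str = "header",
    lineage_tsv: Optional[Union[str, Path]] = None,
) -> ReferenceDB:
    """Read a FASTA reference set (wrapped or single-line) into a ReferenceDB.

    ``annotation_dialect='header'`` (default) takes the lineage from the
    FASTA description after the id; ``'tsv'`` looks each id up in the
    ``lineage_tsv`` sidecar (ids missing from the sidecar load with an
    empty lineage).
    """
    if annotation_dialect not in ("header", "tsv"):
        raise ValueError(f"unknown annotation dialect: {annotation_dialect!r}")
    sidecar = _load_sidecar(lineage_tsv) if annotation_dialect == "tsv" else None
    if annotation_dialect == "tsv" and sidecar is None:  # pragma: no cover
        raise ValueError("tsv dialect requires lineage_tsv")

    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if annotation_dialect == "header":
            rid, lineage = _parse_header_dialect(rec)
        else:
            rid = rec.id
            lineage = sidecar.get(rid, Lineage())
        records.append(ReferenceRecord(id=rid, seq=str(rec.seq), lineage=lineage))
    return ReferenceDB(records)


def write_references(db: ReferenceDB, fasta_path: Union[str, Path]) -> None:
    """Emit single-line FASTA with the lineage in each description."""
    with open(fasta_path, "w") as fh:
        for rec in db:
            fh.write(f">{rec.id} {rec.lineage.to_string()}\n{rec.seq}\n")


def filter_dataset(
    db: ReferenceDB,
    min_len: int = 100,
    require_species: bool = False,
    dedupe: bool = False,
) -> ReferenceDB:
    """Apply the database assembly filters.

    Removes records shorter than ``min_len``; optionally removes records
    not identified to species; optionally keeps only the first of records
    sharing an identical (sequence, species) pair. The dedupe key includes
    the species name on purpose: identically sequenced sister species are
    both retained.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[ReferenceRecord] = []
    seen_pairs: set[tuple[str, str]] = set()
    for rec in db:
        if len(rec.seq) < min_len:
            continue
        species = rec.lineage.name_at("species")
        if require_species and species is None:
            continue
        if dedupe:
            key = (rec.seq, species or "")
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
        kept.append(rec)
    return ReferenceDB(kept)


def leave_one_out_view(db: ReferenceDB, query_id: str) -> ReferenceDB:
    """The database minus exactly the query's own record (db unmodified)."""
    if query_id not in db:
        raise KeyError(f"unknown record id: {query_id!r}")
    return ReferenceDB(r for r in db if r.id != query_id)
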