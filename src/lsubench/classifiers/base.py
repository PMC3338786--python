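"""Shared assignment container and TSV serialization for all classifiers."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from ..taxonomy import RANKS, Lineage, rank_index

__all__ = ["Assignment", "write_assignments_tsv", "read_assignments_tsv"]


@dataclass(frozen=True)
class Assignment:
    """Per-rank taxonomic calls for one query, with optional confidences.

    ``confidences`` (when present) aligns with ``lineage.names``; an empty
    lineage means the query could not be classified, with ``note``
    carrying the diagnostic.
    """

    query_id: str
    lineage: Lineage = Lineage()
    confidences: Optional[tuple[float, ...]] = None
    query_length: Optional[int] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.confidences is not None:
            if len(self.confidences) != len(self.lineage):
                raise ValueError("one confidence per named rank required")
            if any(not 0.0 <= c <= 1.0 for c in self.confidences):
                raise ValueError("confidences must lie in [0, 1]")

    @property
    def is_classified(self) -> bool:
        return len(self.lineage) > 0

    def confidence_at(self, rank: str) -> Optional[float]:
        if self.confidences is None:
            return None
        i = rank_index(rank)
        return self.confidences[i] if i < len(self.confidences) else None

    def name_at(self, rank: str) -> Optional[str]:
        return self.lineage.name_at(rank)


def write_assignments_tsv(
    assignments: Iterable[Assignment], path: Union[str, Path]
) -> None:
    """One row per named rank: query id, rank, taxon, confidence (may be empty)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["query_id", "rank", "taxon", "confidence"])
        for a in assignments:
            if not a.is_classified:
                writer.writerow([a.query_id, "", "", ""])
                continue
            for i, name in enumerate(a.lineage.names):
                conf = "" if a.confidences is None else f"{a.confidences[i]:.4f}"
                writer.writerow([a.query_id, RANKS[i], name, conf])


def read_assignments_tsv(path: Union[str, Path]) -> list[Assignment]:
    """Inverse of :func:`write_assignments_tsv`."""
    rows: dict[str, list[tuple[str, str, str]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for row in reader:
            qid = row[0]
            if qid not in rows:
                rows[qid] = []
                order.append(qid)
            if len(row) >= 3 and row[1]:
                rows[qid].append((row[1], row[2], row[3] if len(row) > 3 else ""))
    out = []
    for qid in order:
        entries = sorted(rows[qid], key=lambda r: rank_index(r[0]))
        names = tuple(e[1] for e in entries)
        confs = tuple(e[2] for e in entries)
        has_conf = all(c != "" for c in confs) and confs
        out.append(
            Assignment(
                query_id=qid,
                lineage=Lineage(names),
                confidences=tuple(float(c) for c in confs) if has_conf else None,
            )
        )
    return out
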