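"""Amplicon read simulation: primer mapping, clipping, per-base error.

Primer binding sites are located by IUPAC-aware sliding-window comparison
on both strands with a small mismatch allowance (default one mismatch, the
convention used when mapping published LSU primers onto reference
sequences). Fixed-length fragments are then clipped in sequencing
direction from the primer's 5' position, per-base substitution errors are
injected, and equal-size mock communities are assembled from parents on
which every primer in a panel can be detected.

Coordinates are 1-based inclusive throughout, matching the convention of
published primer tables; a reverse primer's printed descending range
(e.g. 655-639) corresponds to a minus-strand site whose plus-strand span
is start=639, end=655.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .refdb import ReferenceDB
from .seeding import child_seed

__all__ = [
    "Primer",
    "PrimerSite",
    "SimulatedRead",
    "reverse_complement",
    "find_primer_site",
    "clip_fragment",
    "inject_errors",
    "build_mock_communities",
    "LSU_PRIMERS",
    "BENCHMARK_PRIMER_NAMES",
    "benchmark_primers",
    "read_primer_tsv",
    "write_primer_tsv",
]

# IUPAC degeneracy sets, encoded as 4-bit masks (A=1, C=2, G=4, T=8).
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _bits(seq: str) -> np.ndarray:
    try:
        return np.array([_IUPAC_BITS[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol in sequence: {exc}") from None


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3' with its expected orientation.

    ``published_span`` optionally records the coordinate range at which the
    primer is conventionally mapped (descending for reverse primers).
    """

    name: str
    seq: str
    orientation: str  # "forward" | "reverse"
    published_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if len(seq) < 10:
            raise ValueError(f"primer {self.name}: length must be >= 10")
        bad = set(seq) - set(_IUPAC_BITS)
        if bad:
            raise ValueError(f"primer {self.name}: non-IUPAC symbols {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: bad orientation {self.orientation!r}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


#: Published nuclear LSU rDNA primer panel with coordinates on the
#: S. cerevisiae 25S rDNA frame (descending span = reverse orientation).
LSU_PRIMERS: tuple[Primer, ...] = (
    Primer("LR0R", "ACCCGCTGAACTTAAGC", "forward", (26, 42)),
    Primer("LR1", "AGCATATCAATAAGCGGAGGA", "forward", (40, 60)),
    Primer("NL-1", "GCATATCAATAAGCGGAGGAAAAG", "forward", (41, 64)),
    Primer("LR3R", "GTCTTGAAACACGGACC", "forward", (639, 655)),
    Primer("NL-4", "GGTCCGTGTTTCAAGACGG", "reverse", (655, 637)),
    Primer("TW13", "GGTCCGTGTTTCAAGACG", "reverse", (655, 638)),
    Primer("LR3", "GGTCCGTGTTTCAAGAC", "reverse", (655, 639)),
    Primer("NDL22", "TGGTCCGTGTTTCAAGACG", "reverse", (656, 638)),
    Primer("LR16", "TTCCACCCAAACACTCG", "reverse", (691, 675)),
    Primer("LR5", "ATCCTGAGGGAAACTTC", "reverse", (966, 950)),
    Primer("nLSU1221R", "CTAGATGAACYAACACCTT", "reverse", (1222, 1204)),
    Primer("LR7", "TACTACCACCAAGATCT", "reverse", (1449, 1433)),
)

#: The four-primer panel spanning the 5' LSU region used for benchmarking.
BENCHMARK_PRIMER_NAMES: tuple[str, ...] = ("LR0R", "LR3", "LR5", "LR7")


def benchmark_primers() -> tuple[Primer, ...]:
    by_name = {p.name: p for p in LSU_PRIMERS}
    return tuple(by_name[n] for n in BENCHMARK_PRIMER_NAMES)


def write_primer_tsv(primers: Sequence[Primer], path) -> None:
    """Emit a primer panel as TSV: name, 5'->3' sequence, orientation."""
    with open(path, "w") as fh:
        fh.write("name\tsequence\torientation\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.seq}\t{p.orientation}\n")


def read_primer_tsv(path) -> tuple[Primer, ...]:
    """Load a primer panel written by :func:`write_primer_tsv`."""
    primers = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, seq, orientation = line.split("\t")[:3]
            primers.append(Primer(name, seq, orientation))
    return tuple(primers)


@dataclass(frozen=True)
class PrimerSite:
    """A located binding site on the plus-strand coordinate frame."""

    parent_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive, start <= end
    strand: str  # "+" | "-"
    mismatches: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid site span")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class SimulatedRead:
    """A clipped amplicon fragment with its simulation provenance."""

    id: str
    parent_id: str
    primer: str
    seq: str
    length: int
    strand: str = "+"
    error_count: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.seq) != self.length:
            raise ValueError("read sequence length != declared length")
        if self.error_count > self.length:
            raise ValueError("more errors than positions")


def _scan(seq_bits: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` at every offset (IUPAC-aware).

    A target position matches when its degeneracy set is contained in the
    pattern symbol's set (for plain A/C/G/T targets this is membership).
    """
    m = len(pattern)
    if len(seq_bits) < m:
        return np.empty(0, dtype=np.int32)
    pat = _bits(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, m)
    contained = (windows & ~pat[None, :]) == 0
    return (m - contained.sum(axis=1)).astype(np.int32)


def find_primer_site(
    seq: str,
    primer: Primer,
    max_mismatch: int = 1,
    parent_id: str = "",
) -> Optional[PrimerSite]:
    """Best primer binding site on either strand, or None.

    Scans the sequence with the primer (forward orientation) and with its
    reverse complement (reverse orientation); returns the unique site with
    the fewest mismatches within the allowance. Ties are resolved
    deterministically — expected-orientation strand first, then the
    5'-most start — and flagged ambiguous.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq_bits = _bits(seq)
    m = len(primer)
    candidates: list[tuple[int, int, str]] = []  # (mismatches, start0, strand)
    fwd = _scan(seq_bits, primer.seq)
    for start0 in np.flatnonzero(fwd <= max_mismatch):
        candidates.append((int(fwd[start0]), int(start0), "+"))
    rev = _scan(seq_bits, reverse_complement(primer.seq))
    for start0 in np.flatnonzero(rev <= max_mismatch):
        candidates.append((int(rev[start0]), int(start0), "-"))
    if not candidates:
        return None
    best_mm = min(c[0] for c in candidates)
    best = [c for c in candidates if c[0] == best_mm]
    expected_strand = "+" if primer.orientation == "forward" else "-"
    best.sort(key=lambda c: (c[2] != expected_strand, c[1]))
    mm, start0, strand = best[0]
    ambiguous = len(best) > 1
    if ambiguous:
        warnings.warn(
            f"primer {primer.name}: {len(best)} equally good sites on "
            f"{parent_id or 'sequence'}; keeping {strand} strand at {start0 + 1}",
            stacklevel=2,
        )
    return PrimerSite(
        parent_id=parent_id,
        start=start0 + 1,
        end=start0 + m,
        strand=strand,
        mismatches=mm,
        ambiguous=ambiguous,
    )


def clip_fragment(
    parent_seq: str,
    site: PrimerSite,
    length: int,
    read_id: Optional[str] = None,
    primer_name: str = "",
    include_primer: bool = True,
) -> Optional[SimulatedRead]:
    """Fragment of exactly ``length`` bases in sequencing direction.

    Forward-strand sites read rightwards from the primer's 5' position;
    minus-strand sites read leftwards and the fragment is returned
    reverse-complemented (5'->3' of the sequencing strand). Fragments
    include the primer-binding span at their 5' end unless
    ``include_primer=False``. Returns None when insufficient template
    remains.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    n = len(parent_seq)
    if site.strand == "+":
        start0 = site.start - 1 if include_primer else site.end
        stop0 = start0 + length
        if stop0 > n:
            return None
        frag = parent_seq[start0:stop0]
    else:
        stop0 = site.end if include_primer else site.start - 1
        start0 = stop0 - length
        if start0 < 0:
            return None
        frag = reverse_complement(parent_seq[start0:stop0])
    return SimulatedRead(
        id=read_id or f"{site.parent_id}|{primer_name}|L{length}",
        parent_id=site.parent_id,
        primer=primer_name,
        seq=frag,
        length=length,
        strand=site.strand,
    )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def inject_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Independent per-base substitution with probability ``rate``.

    A substituted base is drawn uniformly from the three alternatives, so
    at rate 1 every position is guaranteed to differ from the original.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("error rate must be in [0, 1]")
    if rate == 0.0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq, 0
    idx = np.flatnonzero(hit)
    originals = arr[idx]
    # choose among the 3 alternatives by skipping the original base
    choice = rng.integers(0, 3, size=n_hit)
    base_rank = np.searchsorted(_BASES, originals)
    # non-ACGT symbols (IUPAC codes) are replaced by any of A/C/G/T
    is_acgt = np.isin(originals, _BASES)
    choice = np.where(is_acgt & (choice >= base_rank), choice + 1, choice)
    arr[idx] = _BASES[np.clip(choice, 0, 3)]
    return arr.tobytes().decode(), n_hit


def build_mock_communities(
    db: ReferenceDB,
    primers: Sequence[Primer],
    length: int,
    rates: Iterable[float],
    seed: int = 0,
    max_mismatch: int = 1,
    include_primer: bool = True,
    max_parents: Optional[int] = None,
) -> tuple[dict[tuple[str, float], list[SimulatedRead]], list[str]]:
    """One equal-size community per (primer, error rate).

    Parents are retained only when every primer in the panel yields a
    valid clip of ``length`` bases, so communities across primers share
    identical parent-id sets. Each (primer, rate) cell gets an independent
    child RNG stream derived from ``seed``. Returns (communities, parent
    ids retained).
    """
    primers = list(primers)
    if not primers:
        raise ValueError("at least one primer required")
    rates = list(rates)
    if not rates:
        raise ValueError("at least one error rate required")

    base_reads: dict[str, dict[str, SimulatedRead]] = {}  # parent -> primer -> read
    retained: list[str] = []
    for rec in db:
        per_primer: dict[str, SimulatedRead] = {}
        for primer in primers:
            site = find_primer_site(rec.seq, primer, max_mismatch, parent_id=rec.id)
            if site is None:
                break
            read = clip_fragment(
                rec.seq, site, length,
                primer_name=primer.name, include_primer=include_primer,
            )
            if read is None:
                break
            per_primer[primer.name] = read
        else:
            base_reads[rec.id] = per_primer
            retained.append(rec.id)
            if max_parents is not None and len(retained) >= max_parents:
                break
    if not retained:
        raise ValueError("no parent passes all primers at this length")

    communities: dict[tuple[str, float], list[SimulatedRead]] = {}
    for primer in primers:
        for rate in rates:
            rng = np.random.default_rng(
                child_seed(seed, "mock", primer.name, repr(rate), length)
            )
            reads = []
            for pid in retained:
                base = base_reads[pid][primer.name]
                mutated, n_err = inject_errors(base.seq, rate, rng)
                reads.append(
                    SimulatedRead(
                        id=f"{pid}|{primer.name}|L{length}|r{rate:g}",
                        parent_id=pid,
                        primer=primer.name,
                        seq=mutated,
                        length=length,
                        strand=base.strand,
                        error_count=n_err,
                        error_rate=rate,
                    )
                )
            communities[(primer.name, rate)] = reads
    return communities, retained
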