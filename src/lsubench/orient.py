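"""Query strand orientation against reference sequences.

Amplicon reads clipped from reverse primers arrive reverse-complemented
relative to the reference strand. All classifiers orient each query
before scoring: the query and its reverse complement are compared (by
infix edit distance) against a small sample of references and the
orientation with the closer best match wins. The two orientations differ
enormously in distance for any genuine rDNA read, so a handful of
references suffices.
"""

from __future__ import annotations

from typing import Sequence

import edlib

from .reads import reverse_complement

__all__ = ["orient_query"]


def _best_distance(query: str, refs: Sequence[str]) -> int:
    best = None
    for ref in refs:
        d = edlib.align(query, ref, mode="HW", task="distance")["editDistance"]
        if d >= 0 and (best is None or d < best):
            best = d
    return best if best is not None else len(query)


def orient_query(seq: str, refs: Sequence[str]) -> tuple[str, str]:
    """Return (oriented sequence, strand) with strand '+' or '-'.

    '-' means the reverse complement aligned better and was returned.
    Ties keep the input orientation.
    """
    fwd = _best_distance(seq, refs)
    rc = reverse_complement(seq)
    rev = _best_distance(rc, refs)
    if rev < fwd:
        return rc, "-"
    return seq, "+"
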