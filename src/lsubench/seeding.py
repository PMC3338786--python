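"""Deterministic seed fan-out.

One root seed is hashed together with stage/dataset labels so that every
stochastic stage gets an independent, reproducible stream and adding a new
stage never perturbs the randomness of existing ones.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(root_seed: int, *labels: object) -> int:
    """Stable child seed (< 2**31) derived from a root seed and labels."""
    h = hashlib.sha256()
    h.update(str(int(root_seed)).encode())
    for label in labels:
        h.update(b"\x1f")
        h.update(str(label).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
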