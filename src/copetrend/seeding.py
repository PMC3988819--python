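"""Stable derivation of child seeds from one master seed.

Every stochastic stage (tree calibration replicate, trait simulation,
bootstrap, optimizer start points) draws its generator from
``child_seed(master, *tags)`` so that stages are independently
reproducible: re-running one stage with the same tags gives the same
stream regardless of what ran before it.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(master: int, *tags) -> int:
    """Derive a deterministic 31-bit seed from a master seed and string/int tags.

    Uses SHA-256 of the tag tuple rather than Python's ``hash`` (which is
    salted per process and therefore not reproducible).
    """
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for t in tags:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31 - 1)


def rng_for(master: int, *tags) -> np.random.Generator:
    """Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *tags))
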