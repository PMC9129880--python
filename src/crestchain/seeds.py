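"""Deterministic seed derivation.

All randomness in the package flows from a single master seed.  Stage,
replicate and per-agent streams are derived by stable hashing so that results
are independent of execution order and reproducible across processes.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31


def derive_seed(master: int, *parts: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and a label path.

    The same ``(master, parts)`` always yields the same child seed; distinct
    label paths yield effectively independent seeds.
    """
    key = ":".join([str(int(master))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def derive_rng(master: int, *parts: object) -> np.random.Generator:
    """A numpy Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *parts))
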