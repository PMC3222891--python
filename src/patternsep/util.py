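"""Seed derivation and small shared helpers.

Per-stage random streams are derived from the master seed by stable hashing
of ``(seed, stage_name, participant_id, ...)`` so that adding participants or
stages never shifts existing streams.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master_seed: int, *parts) -> int:
    """Derive a child seed from a master seed and a sequence of string keys.

    Uses SHA-256 of the pipe-joined decimal/master representation, reduced
    mod 2**31 so the result is always a small positive int.
    """
    key = "|".join([str(int(master_seed))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)


def derive_rng(master_seed: int, *parts) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *parts))
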