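"""Deterministic seed derivation.

One top-level integer seed drives every stochastic stage; each stage (and each
unit of work inside a stage, e.g. one delta of a power grid) derives a child
``numpy.random.Generator`` from the top-level seed plus a stable key, so results
are reproducible and independent of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "key_to_int"]


def key_to_int(key: int | str) -> int:
    """Map a stage key to a stable non-negative integer (CRC32 for strings)."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for stage ``keys`` derived from the top-level seed."""
    entropy = [int(seed) & 0xFFFFFFFF, *(key_to_int(k) for k in keys)]
    return np.random.default_rng(np.random.SeedSequence(entropy))
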