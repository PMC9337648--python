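"""Deterministic seed splitting.

Every stochastic stage derives its own :class:`numpy.random.Generator` from a
single master seed plus a tuple of string/int tags, so regenerating any part
of a study (one sweep, one caliper read) never depends on generation order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["split_rng", "spawn_key"]


def spawn_key(*tags: str | int) -> tuple[int, ...]:
    """Map a tuple of tags to a stable tuple of uint32 spawn keys."""
    key = []
    for tag in tags:
        if isinstance(tag, (int, np.integer)):
            key.append(int(tag) & 0xFFFFFFFF)
        else:
            key.append(zlib.crc32(str(tag).encode("utf-8")))
    return tuple(key)


def split_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """A generator unique to (seed, *tags), independent of call order."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key(*tags))
    return np.random.Generator(np.random.PCG64(ss))
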