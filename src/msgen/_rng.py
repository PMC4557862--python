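"""Deterministic per-stage random streams.

Every stochastic stage derives its generator from one global integer seed
plus a string key, so adding or reordering stages never perturbs the draws
of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator keyed by (seed, *keys).

    The keys are hashed with CRC32 so the entropy pool is stable across
    processes and Python versions (unlike the builtin ``hash``).
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))
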