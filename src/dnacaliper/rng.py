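"""Counter-based random-stream derivation.

A single user seed is split into named, independent streams so that each
stage of a simulation or analysis can be rerun in isolation and still
reproduce exactly the numbers it produced inside a full run.
"""
from __future__ import annotations

import zlib

import numpy as np


def rng_stream(seed: int, *keys: object) -> np.random.Generator:
    """Return a generator for the stream identified by ``keys`` under ``seed``.

    The stream identity is stable across processes and platforms: each key is
    hashed with CRC-32 and combined with the seed in a ``SeedSequence``.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(repr(k).encode("utf-8")) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))
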