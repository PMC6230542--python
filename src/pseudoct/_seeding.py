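"""Deterministic seed fan-out.

A single master seed is expanded into named, order-independent substreams
(phantom geometry, projection noise, weight init, epoch shuffling) so any
stage can be re-run in isolation and still reproduce bit-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "rng_for"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key)


def substream(master_seed: int, *keys: int | str) -> np.random.SeedSequence:
    """A reproducible SeedSequence for the substream named by ``keys``.

    The same (master_seed, keys) always yields the same stream; distinct
    key paths yield statistically independent streams.
    """
    entropy = (int(master_seed),) + tuple(_key_to_int(k) for k in keys)
    return np.random.SeedSequence(entropy)


def rng_for(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Generator seeded from the named substream."""
    return np.random.default_rng(substream(master_seed, *keys))
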