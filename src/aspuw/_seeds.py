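"""Deterministic, order-independent seed derivation.

A master integer seed plus a tuple of string/int keys maps to a
``numpy.random.Generator``.  String keys are hashed with CRC-32 so the
stream depends only on the key values, never on iteration order or the
Python hash seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_entropy"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_entropy(master_seed: int, *keys) -> list[int]:
    return [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]


def derive_rng(master_seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(derive_entropy(master_seed, *keys)))
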