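"""Deterministic random streams.

One root seed; every component derives its own child stream from a fixed
string label, so regenerating one component never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]

_MOD = 2**31 - 1


def child_seed(root_seed: int, label: str) -> int:
    """Derive a stable child seed (< 2**31) from a root seed and a label."""
    mix = zlib.crc32(label.encode("utf-8")) ^ (root_seed * 0x9E3779B1 & 0xFFFFFFFF)
    return int(mix % _MOD)


def child_rng(root_seed: int, label: str) -> np.random.Generator:
    """A numpy Generator seeded from ``(root_seed, label)``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=root_seed, spawn_key=(zlib.crc32(label.encode()),))
    )
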