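"""Seed policy: one master seed, named child streams.

Every stochastic operation draws from a dedicated child generator derived from
the master seed and a stable string key, so replicates and pipeline stages are
independently reproducible no matter the order in which they run.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the stream named by `keys` under master `seed`.

    Keys are hashed with crc32 (stable across processes, unlike ``hash``).
    """
    spawn = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn))
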