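"""Seed-substream management.

One global integer seed drives the whole pipeline; every stochastic operation
derives an independent, named substream so that stages can be re-run (or run in
isolation) without perturbing each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *keys)``.

    String keys are hashed with CRC32 so the mapping is stable across runs and
    platforms; integer keys are used as-is.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            words.append(int(k) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(words))
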