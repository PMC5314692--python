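"""Deterministic per-stage seed derivation from one global seed.

Every pipeline stage draws from its own generator, seeded by a CRC32 hash
of ``"<seed>:<stage>"``. Stages are therefore independently reproducible:
re-running only the sampling stage with the same global seed yields the
same numbers regardless of what ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(seed: int, stage: str) -> int:
    """A stable 31-bit sub-seed for a named stage."""
    return int(zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))
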