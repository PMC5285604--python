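"""Deterministic RNG stream derivation.

Every stochastic stage derives its generator from (global seed, stage label)
so that pipeline stages are reproducible independently of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(seed: int, label: str) -> int:
    """A stable 31-bit seed for a named stage, derived from the global seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stage_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, label))
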