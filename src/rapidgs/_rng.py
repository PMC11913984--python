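"""Seed-derivation helpers.

Every stochastic operation takes either an integer seed or a
``numpy.random.Generator``.  Scheme-level code derives one child stream per
named stage from a master seed so that reruns are bit-reproducible and
stages can be re-executed in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["as_rng", "stage_rng", "stage_seed"]


def as_rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed (or None) to a Generator; pass Generators through."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic 63-bit sub-seed for a named stage."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") >> 1


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))
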