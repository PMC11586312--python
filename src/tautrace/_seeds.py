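"""Seed handling.

A single user-facing integer seed fans out to per-stage child generators
through :class:`numpy.random.SeedSequence.spawn`.  Child i of seed s is
``default_rng(SeedSequence(s).spawn(n)[i])``; the rule is deterministic and
collision-free across stages, so identical seeds reproduce every stage
bit-for-bit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rngs", "child_seed_sequences"]


def child_seed_sequences(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Split ``seed`` into ``n`` independent child seed sequences."""
    return np.random.SeedSequence(seed).spawn(n)


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split ``seed`` into ``n`` independent :class:`numpy.random.Generator`."""
    return [np.random.default_rng(ss) for ss in child_seed_sequences(seed, n)]
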