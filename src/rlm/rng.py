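"""Seed plumbing: every stochastic operation takes a seed or Generator.

A single master seed is split into independent per-stage streams with
`numpy.random.SeedSequence.spawn`, so reruns with the same master seed are
bit-identical while stages stay statistically independent.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def split_rngs(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one seed."""
    if isinstance(seed, np.random.Generator):
        seqs = seed.bit_generator.seed_seq.spawn(n)
    elif isinstance(seed, np.random.SeedSequence):
        seqs = seed.spawn(n)
    else:
        seqs = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]
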