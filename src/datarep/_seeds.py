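"""Deterministic seed derivation.

A single master seed is expanded into independent child seeds through
NumPy's counter-based ``SeedSequence``, so replicates are reproducible
and mutually independent regardless of execution order.  Children are
kept below 2**31 so they are valid seeds for every scikit-learn
estimator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seeds", "child_rng"]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from ``master_seed``."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """A generator keyed by the master seed plus an integer path."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
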