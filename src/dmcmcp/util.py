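"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def as_rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed (or an existing Generator) into a ``numpy.random.Generator``.

    Every stochastic operation in this package routes its randomness through
    this helper, so there is no hidden global RNG state anywhere.
    """
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance between two probability vectors: ``0.5 * sum|p - q|``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    return 0.5 * float(np.abs(p - q).sum())
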