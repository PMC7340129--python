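"""Small shared helpers: deterministic seed derivation and rounding."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "largest_remainder", "round_half_up"]


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and a tag path.

    All stochastic components draw their seeds through this one function so
    that a single master seed pins the entire pipeline, while distinct stages
    (splits, CV, classifiers, bootstraps, label shuffles) get decorrelated
    streams.
    """
    key = repr((int(master),) + tuple(tags)).encode()
    digest = hashlib.blake2b(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for positive x)."""
    return int(np.floor(x + 0.5))


def largest_remainder(fractions, total: int) -> list[int]:
    """Apportion `total` into integer parts proportional to `fractions`.

    Floors the ideal shares, then hands the remaining units to the parts
    with the largest fractional remainders (ties to the earlier part).
    """
    fractions = np.asarray(fractions, dtype=float)
    ideal = fractions / fractions.sum() * total
    base = np.floor(ideal).astype(int)
    remainder = ideal - base
    short = total - int(base.sum())
    order = np.argsort(-remainder, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()
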