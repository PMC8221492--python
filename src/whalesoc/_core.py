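"""Shared primitives: permutation-test containers, p-value and RNG conventions.

All empirical p-values in this package use the add-one convention
``p = (count + 1) / (n_iter + 1)`` so that no test can report exactly zero.
All randomness flows from ``numpy.random.Generator`` objects; functions accept
either a Generator or an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["PermutationResult", "empirical_p", "as_rng"]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator; integers (and None) are passed to ``default_rng``."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def empirical_p(observed: float, null: np.ndarray, alternative: str = "greater") -> float:
    """Add-one empirical p-value of ``observed`` against a null sample.

    alternative: "greater" (null >= observed counts), "less", or "two-sided"
    (twice the smaller tail, capped at 1).
    """
    null = np.asarray(null, dtype=float)
    n = null.size
    if n == 0:
        raise ValueError("empty null distribution")
    hi = (np.sum(null >= observed) + 1) / (n + 1)
    lo = (np.sum(null <= observed) + 1) / (n + 1)
    if alternative == "greater":
        return float(hi)
    if alternative == "less":
        return float(lo)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * min(hi, lo)))
    raise ValueError(f"unknown alternative: {alternative!r}")


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the resulting p-value.

    ``statistic`` and ``p_value`` may be scalars or arrays (e.g. per-lag or
    per-bin tests); ``extras`` carries test-specific side products such as
    secondary statistics or envelopes.
    """

    statistic: Any
    null: np.ndarray
    p_value: Any
    n_iter: int
    alternative: str = "greater"
    extras: dict = field(default_factory=dict)
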