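"""Default penalty parameters from data scale, problem size and sharing.

The guideline rules are

    lam1_i = c1 * sigma_i
    lam2_i = rho(p) * c2 * sigma_i * sqrt(log N)
    lam3_i = (1 - rho(p)) * c3 * sigma_i * sqrt(p * M * log N)

where sigma_i is the robust per-sequence noise SD, N the probe count (the
possible number of jumps; the sqrt(log N) factor has a multiple-comparison
controlling effect), M the number of jointly analyzed sequences, and p the
anticipated proportion of sequences carrying a shared CNV.  The weight
rho(p) trades the within-sequence fusion penalty off against the group
penalty: p = 1 (e.g. LRR and mBAF of one subject) gives rho = 0 and pure
group fusion; p = 0 (unrelated sequences) gives rho = 1 and independent
fusion.  Only the endpoints are constrained; the default rho is the linear
interpolant 1 - p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .gfl_solver import PenaltyConfig

__all__ = ["TuningInputs", "rho", "default_penalties"]


def rho(p: float) -> float:
    """Fusion-vs-group weight: 1 - p (linear, matching both endpoints)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return 1.0 - p


@dataclass
class TuningInputs:
    """Inputs to the default penalty rules.

    ``c1`` defaults to 0.1 so that lam1 is about 0.1 on unit-noise signals,
    the working value for diploid-baseline shrinkage; ``c2`` and ``c3``
    default to 1 and should be adjusted for unusual signal-to-noise ratios
    or CNV sizes.
    """

    sigma: np.ndarray
    N: int
    M: int
    p: float
    c1: float = 0.1
    c2: float = 1.0
    c3: float = 1.0
    rho_fn: Callable[[float], float] = rho

    def __post_init__(self) -> None:
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sigma < 0):
            raise ValueError("sigma must be non-negative")
        if sigma.size not in (1, self.M):
            raise ValueError("sigma must be scalar or length M")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if min(self.c1, self.c2, self.c3) <= 0:
            raise ValueError("multipliers c1, c2, c3 must be positive")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        self.sigma = np.broadcast_to(sigma, (self.M,)).copy()


def default_penalties(
    t: TuningInputs,
    epsilon: float = 1e-8,
    tol: float = 1e-6,
    max_iter: int = 500,
    jump_weights: np.ndarray | None = None,
) -> PenaltyConfig:
    """Apply the guideline rules, returning a ready solver configuration."""
    r = t.rho_fn(t.p)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"rho(p) must be in [0, 1], got {r}")
    logN = np.log(t.N)
    lam1 = t.c1 * t.sigma
    lam2 = r * t.c2 * t.sigma * np.sqrt(logN)
    lam3 = (1.0 - r) * t.c3 * t.sigma * np.sqrt(t.p * t.M * logN)
    return PenaltyConfig(
        lambda1=lam1,
        lambda2=lam2,
        lambda3=lam3,
        epsilon=epsilon,
        tol=tol,
        max_iter=max_iter,
        jump_weights=jump_weights,
    )
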