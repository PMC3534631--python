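"""Five-state copy-number calling by per-segment likelihood ratio.

Each constant-mean segment R of one subject is assigned a copy-number
state c in {0, 1, 2, 3, 4} by comparing, against the diploid state 2, the
joint likelihood of its BAF values x_R and LRR values y_R:

    LR(c) = log L_BAF(x_R; c) / L_BAF(x_R; 2)
          + log L_LRR(y_R; c) / L_LRR(y_R; 2),     c = 0, 1, 3, 4.

The maximizing state c_hat is accepted only if LR(c_hat) > r1 and the
absolute LRR segment mean exceeds r2 * sigma — the latter guard prevents
long segments with a small artifactual mean offset from being promoted out
of the diploid state by sheer probe count.  Rejected segments are reported
as CN = 2 with the reason.

The state model mirrors the canonical genotyping-array patterns: LRR is
normal around a state-specific mean (deletions negative, duplications
positive, saturating with copy count); BAF is a mixture over genotype
clusters at fractions k/c with binomial(c, p_B) weights, a small uniform
outlier component, and — because array software clips BAF to [0, 1] — the
mass of boundary clusters that noise pushes past the edge sits as a point
mass exactly at 0 or 1.  Homozygous deletions (c = 0) have no alleles to
measure, so their BAF is uniform noise.  Likelihoods are densities with
respect to Lebesgue measure on (0, 1) plus atoms at {0, 1}, identically
for every state, so the ratios are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signal_model import InsufficientDataError

__all__ = [
    "StateModel",
    "CallingConfig",
    "CNCall",
    "state_loglik",
    "likelihood_ratio",
    "call_segment",
]

STATES = (0, 1, 2, 3, 4)
ALT_STATES = (0, 1, 3, 4)

# floor on the per-probe likelihood: keeps a single wild value from
# producing -inf and vetoing a whole segment
_DENSITY_FLOOR = 1e-12


@dataclass
class StateModel:
    """Per-state signal distributions for the five copy-number states.

    ``lrr_means`` are the expected LRR levels for c = 0..4 (log2-ratio
    units; the homozygous-deletion level is array-saturated rather than
    -inf); ``lrr_sd`` the common LRR noise SD.  BAF clusters sit at k/c for
    k = 0..c with binomial(c, ``p_b``) weights; ``baf_sd_boundary`` applies
    to the clusters at 0/1 and ``baf_sd_interior`` to the rest;
    ``outlier_frac`` is a uniform-on-[0,1] contamination component.
    """

    lrr_means: tuple[float, ...] = (-3.0, -0.66, 0.0, 0.40, 0.68)
    lrr_sd: float = 0.2
    p_b: float = 0.5
    baf_sd_boundary: float = 0.03
    baf_sd_interior: float = 0.05
    outlier_frac: float = 0.01

    def __post_init__(self) -> None:
        if len(self.lrr_means) != 5:
            raise ValueError("lrr_means must give one level per state 0..4")
        if self.lrr_sd <= 0 or self.baf_sd_boundary <= 0 or self.baf_sd_interior <= 0:
            raise ValueError("SDs must be positive")
        if not 0 <= self.outlier_frac < 1:
            raise ValueError("outlier_frac must be in [0, 1)")
        if not 0 < self.p_b < 1:
            raise ValueError("p_b must be in (0, 1)")

    def baf_clusters(self, c: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cluster centers, mixture weights and SDs for state ``c`` (c >= 1)."""
        k = np.arange(c + 1)
        centers = k / c
        weights = stats.binom.pmf(k, c, self.p_b)
        sds = np.where(
            (centers == 0.0) | (centers == 1.0),
            self.baf_sd_boundary,
            self.baf_sd_interior,
        )
        return centers, weights, sds


@dataclass
class CallingConfig:
    """Acceptance thresholds: r1 on the LR, r2 on the LRR mean shift.

    ``r2_dup`` and ``r2_del`` are in units of the sample's LRR noise SD;
    deletions use the stricter default because their larger state means
    leave room for it.
    """

    r1: float = 10.0
    r2_dup: float = 1.0
    r2_del: float = 1.5

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2_dup <= 0 or self.r2_del <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CNCall:
    """Outcome of calling one segment."""

    state: int
    lr: dict[int, float] = field(default_factory=dict)
    accepted: bool = False
    reason: str = "none"
    lrr_mean: float = np.nan


def _baf_log_density(x: np.ndarray, c: int, model: StateModel) -> np.ndarray:
    """Per-probe BAF log density under state ``c`` (mixed measure, see module doc)."""
    x = np.asarray(x, dtype=float)
    at0 = x <= 0.0
    at1 = x >= 1.0
    interior = ~(at0 | at1)
    dens = np.zeros_like(x)

    w_sig = 1.0 - model.outlier_frac
    if c == 0:
        # no DNA: BAF is pure measurement noise, modeled uniform on (0, 1)
        dens[interior] += w_sig + model.outlier_frac
    else:
        centers, weights, sds = model.baf_clusters(c)
        for mu, w, sd in zip(centers, weights, sds):
            if mu == 0.0:
                dens[at0] += w_sig * w * 0.5  # clipped half of the cluster
                dens[interior] += w_sig * w * stats.norm.pdf(x[interior], 0.0, sd)
            elif mu == 1.0:
                dens[at1] += w_sig * w * 0.5
                dens[interior] += w_sig * w * stats.norm.pdf(x[interior], 1.0, sd)
            else:
                dens[interior] += w_sig * w * stats.norm.pdf(x[interior], mu, sd)
        dens[interior] += model.outlier_frac
    return np.log(np.maximum(dens, _DENSITY_FLOOR))


def state_loglik(
    baf: np.ndarray | None,
    lrr: np.ndarray | None,
    c: int,
    model: StateModel,
) -> float:
    """Segment log likelihood under state ``c``; missing entries are dropped."""
    if c not in STATES:
        raise ValueError(f"state must be one of {STATES}, got {c}")
    total = 0.0
    n = 0
    if baf is not None:
        x = np.asarray(baf, dtype=float)
        x = x[np.isfinite(x)]
        n += x.size
        if x.size:
            total += float(np.sum(_baf_log_density(x, c, model)))
    if lrr is not None:
        y = np.asarray(lrr, dtype=float)
        y = y[np.isfinite(y)]
        n += y.size
        if y.size:
            total += float(
                np.sum(stats.norm.logpdf(y, model.lrr_means[c], model.lrr_sd))
            )
    if n == 0:
        raise InsufficientDataError("empty segment: no observed BAF or LRR values")
    return total


def likelihood_ratio(
    baf: np.ndarray | None, lrr: np.ndarray | None, model: StateModel
) -> dict[int, float]:
    """LR(c) = loglik(c) - loglik(2) for the four non-diploid states."""
    base = state_loglik(baf, lrr, 2, model)
    return {c: state_loglik(baf, lrr, c, model) - base for c in ALT_STATES}


def _argmax_state(lr: dict[int, float]) -> int:
    # deterministic tie-break: prefer the state closer to diploid;
    # on an exact-distance tie (0 vs 4) prefer the deletion
    return max(lr, key=lambda c: (lr[c], -abs(c - 2), -c))


def call_segment(
    baf: np.ndarray | None,
    lrr: np.ndarray,
    model: StateModel,
    cfg: CallingConfig = CallingConfig(),
    sigma: float | None = None,
) -> CNCall:
    """Assign a copy-number state to one segment with the r1/r2 guards.

    ``sigma`` is the calling sample's LRR noise SD (defaults to the model's
    ``lrr_sd``); the mean-shift guard compares |mean(lrr)| with r2 * sigma,
    using ``r2_dup`` for gains and ``r2_del`` for losses.
    """
    sigma = model.lrr_sd if sigma is None else float(sigma)
    lr = likelihood_ratio(baf, lrr, model)
    c_hat = _argmax_state(lr)
    y = np.asarray(lrr, dtype=float)
    y = y[np.isfinite(y)]
    lrr_mean = float(y.mean()) if y.size else np.nan

    if lr[c_hat] <= cfg.r1:
        return CNCall(state=2, lr=lr, accepted=False, reason="lr_below_r1", lrr_mean=lrr_mean)
    r2 = cfg.r2_dup if c_hat > 2 else cfg.r2_del
    if not np.isfinite(lrr_mean) or abs(lrr_mean) <= r2 * sigma:
        return CNCall(
            state=2, lr=lr, accepted=False, reason="mean_shift_below_r2", lrr_mean=lrr_mean
        )
    return CNCall(state=c_hat, lr=lr, accepted=True, reason="none", lrr_mean=lrr_mean)
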