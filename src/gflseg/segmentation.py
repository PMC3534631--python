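"""Two-stage segmentation: lax penalized fit, then hard jump thresholding.

With small CNVs (a handful of probes) the asymptotically motivated penalty
levels over-smooth, so segmentation proceeds in two stages: (1) fit the
fused-lasso model with deliberately lax penalties, (2) keep only the jumps
of the fitted means that survive a data-driven threshold.  Two thresholds
are provided: the default "ruler" heuristic, which scales a cut-off by the
largest observed jump clamped to [a*sigma, b*sigma], and a modified-BIC
model selection over nested change-point sets ordered by jump size.
Surviving jumps partition each sequence into segments whose means are
recomputed from the observed data (the penalized fit shrinks levels; the
raw segment average does not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_model import SignalMatrix

__all__ = [
    "JumpSet",
    "ThresholdConfig",
    "extract_jumps",
    "ruler_threshold",
    "mbic_threshold",
    "jumps_to_segments",
    "union_changepoints",
]


@dataclass
class JumpSet:
    """Per-sequence candidate change points.

    ``indices[i]`` holds the 0-based column indices j (1 <= j <= N-1) where
    sequence i jumps between probes j-1 and j; ``sizes[i]`` the signed jump
    beta_ij - beta_{i,j-1}.  ``n_probes`` is the grid length N.
    """

    indices: list[np.ndarray]
    sizes: list[np.ndarray]
    n_probes: int

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.sizes):
            raise ValueError("indices and sizes must align per sequence")
        for idx, sz in zip(self.indices, self.sizes):
            if len(idx) != len(sz):
                raise ValueError("indices and sizes must have equal length")
            if len(idx) and (idx.min() < 1 or idx.max() > self.n_probes - 1):
                raise ValueError("jump indices must lie in 1..N-1")
            if len(idx) > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError("jump indices must be strictly increasing")

    @property
    def M(self) -> int:
        return len(self.indices)


@dataclass
class ThresholdConfig:
    """Ruler constants and threshold method.

    The ruler gamma_i = max(a*sigma_i, min(D_i, b*sigma_i)) reflects the
    scale of a plausible real jump (D_i is the largest fitted jump of
    sequence i); jumps below c*gamma_i are discarded.  Defaults a=1, b=5,
    c=0.2 are the working constants for both tumor and germline data.
    """

    a: float = 1.0
    b: float = 5.0
    c: float = 0.2
    method: str = "ruler"

    def __post_init__(self) -> None:
        if not 0 < self.a < self.b:
            raise ValueError("need 0 < a < b")
        if not 0 < self.c < 1:
            raise ValueError("need 0 < c < 1")
        if self.method not in ("ruler", "mbic"):
            raise ValueError("method must be 'ruler' or 'mbic'")


def extract_jumps(beta: np.ndarray, floor: float | np.ndarray = 0.0) -> JumpSet:
    """First differences of the fitted means above a numerical floor.

    The smoothed solver returns near-zero rather than exactly zero
    differences on flat stretches, so ``floor`` (scalar or per-sequence,
    typically 1e-6 * sigma_i) separates numerical noise from candidates.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    M, N = beta.shape
    floor = np.broadcast_to(np.atleast_1d(np.asarray(floor, dtype=float)), (M,))
    diffs = np.diff(beta, axis=1)
    indices, sizes = [], []
    for i in range(M):
        keep = np.abs(diffs[i]) > floor[i]
        idx = np.nonzero(keep)[0] + 1
        indices.append(idx)
        sizes.append(diffs[i][idx - 1])
    return JumpSet(indices=indices, sizes=sizes, n_probes=N)


def ruler_threshold(
    jumps: JumpSet, sigma: np.ndarray, tc: ThresholdConfig = ThresholdConfig()
) -> JumpSet:
    """Keep jumps exceeding c * gamma_i with the per-sequence ruler gamma_i."""
    sigma = np.broadcast_to(
        np.atleast_1d(np.asarray(sigma, dtype=float)), (jumps.M,)
    )
    indices, sizes = [], []
    for i in range(jumps.M):
        idx, sz = jumps.indices[i], jumps.sizes[i]
        if len(idx) == 0:
            indices.append(idx)
            sizes.append(sz)
            continue
        if sigma[i] <= 0:
            raise ValueError(f"sequence {i}: sigma must be > 0 to set the ruler")
        D = np.max(np.abs(sz))
        gamma = max(tc.a * sigma[i], min(D, tc.b * sigma[i]))
        keep = np.abs(sz) > tc.c * gamma
        indices.append(idx[keep])
        sizes.append(sz[keep])
    return JumpSet(indices=indices, sizes=sizes, n_probes=jumps.n_probes)


def _segment_rss(y: np.ndarray, bounds: np.ndarray) -> tuple[float, np.ndarray]:
    """Residual sum of squares of piecewise means with given breakpoints."""
    edges = np.concatenate(([0], bounds, [len(y)]))
    rss = 0.0
    lengths = np.diff(edges)
    for s, e in zip(edges[:-1], edges[1:]):
        seg = y[s:e]
        rss += float(np.sum((seg - seg.mean()) ** 2))
    return rss, lengths


def mbic_threshold(
    y: np.ndarray,
    candidates: np.ndarray,
    sizes: np.ndarray | None = None,
    penalty: float = 1.5,
    max_k: int = 50,
) -> np.ndarray:
    """Select change points by modified BIC over nested candidate sets.

    Candidates are ranked by |jump| (descending; ties broken by earlier
    index) and added one at a time; for each k the normal-means criterion

        mBIC(k) = (n/2) log(RSS_0 / RSS_k)
                  - 1/2 sum_u log(L_u / n) - penalty * k * log(n)

    is evaluated on the observed values ``y`` (L_u are segment lengths) and
    the k maximizing it is kept; k = 0 (no change points) is allowed.
    Returns the retained candidate indices, sorted ascending.

    The search stops at ``max_k`` change points: the profile-likelihood
    term degenerates as k approaches n (the saturated model drives RSS to
    zero), and realistic change-point counts sit far below the cap.
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    n = len(y)
    candidates = np.asarray(candidates, dtype=int)
    if len(candidates) == 0 or n < 2:
        return candidates[:0]
    if sizes is None:
        order = np.arange(len(candidates))
    else:
        sizes = np.asarray(sizes, dtype=float)
        # stable sort on -|size| keeps earlier indices first among ties
        order = np.argsort(-np.abs(sizes), kind="stable")
    ranked = candidates[order]

    rss0, _ = _segment_rss(y, np.array([], dtype=int))
    best_k, best_score = 0, 0.0
    logn = np.log(n)
    for k in range(1, min(len(ranked), max_k) + 1):
        bounds = np.sort(ranked[:k])
        rss_k, lengths = _segment_rss(y, bounds)
        if rss_k <= 0 or rss0 <= 0:
            break  # saturated fit: profile likelihood no longer informative
        score = (
            0.5 * n * np.log(rss0 / rss_k)
            - 0.5 * np.sum(np.log(lengths / n))
            - penalty * k * logn
        )
        if score > best_score:
            best_k, best_score = k, score
    return np.sort(ranked[:best_k])


def jumps_to_segments(
    jumps: JumpSet,
    data: SignalMatrix,
    beta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Materialize the per-sequence partition implied by the retained jumps.

    Returns a table with 1-based inclusive probe indices, genomic bp span,
    the number of observed probes, and the segment mean recomputed as the
    average of the observed data (not the shrunken fit).  Segments with no
    observed probe inherit the fitted level (if ``beta`` is given) and are
    flagged via ``n_probes == 0``.
    """
    if jumps.n_probes != data.N:
        raise ValueError("jump set and data are on different grids")
    rows = []
    pos = data.grid.positions
    for i in range(jumps.M):
        edges = np.concatenate(([0], jumps.indices[i], [data.N]))
        for s, e in zip(edges[:-1], edges[1:]):
            obs = data.mask[i, s:e]
            n_obs = int(obs.sum())
            if n_obs > 0:
                mean = float(data.values[i, s:e][obs].mean())
            elif beta is not None:
                mean = float(np.mean(np.atleast_2d(beta)[i, s:e]))
            else:
                mean = np.nan
            rows.append(
                {
                    "sample": data.labels[i],
                    "chrom": data.grid.chrom,
                    "start_probe": s + 1,
                    "end_probe": e,
                    "start_bp": int(pos[s]),
                    "end_bp": int(pos[e - 1]),
                    "n_probes": n_obs,
                    "mean": mean,
                }
            )
    return pd.DataFrame(rows)


def union_changepoints(jumpsets: list[JumpSet]) -> JumpSet:
    """Combine change points across signals of the same sample group.

    All listed jump sets must live on the same probe grid; the union of
    their change-point indices defines a finer common segmentation, applied
    to every sequence of the first set.  The recorded size at each index is
    the largest absolute jump observed there across inputs.
    """
    if not jumpsets:
        raise ValueError("need at least one jump set")
    N = jumpsets[0].n_probes
    if any(js.n_probes != N for js in jumpsets):
        raise ValueError("jump sets are on different grids")
    size_at: dict[int, float] = {}
    for js in jumpsets:
        for idx, sz in zip(js.indices, js.sizes):
            for j, s in zip(idx, sz):
                if int(j) not in size_at or abs(s) > abs(size_at[int(j)]):
                    size_at[int(j)] = float(s)
    union = np.array(sorted(size_at), dtype=int)
    sizes = np.array([size_at[j] for j in union])
    M = jumpsets[0].M
    return JumpSet(
        indices=[union.copy() for _ in range(M)],
        sizes=[sizes.copy() for _ in range(M)],
        n_probes=N,
    )
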