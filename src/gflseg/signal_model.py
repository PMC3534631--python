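"""Domain types for multi-sequence copy-number signals on a shared probe grid.

A genotyping array reports, per probe, a total-intensity signal (Log R
Ratio, LRR; ~0 at diploid copy number) and an allelic-ratio signal
(B Allele Frequency, BAF; clustered at genotype fractions).  Both are
modeled as noisy piecewise-constant sequences.  This module provides the
containers for such signals (:class:`ProbeGrid`, :class:`SignalMatrix`),
the mirrored-BAF transform that turns allelic imbalance into a mean-shift
signal, a robust first-difference noise estimator, and the stacking of
sequences measured at non-identical genomic positions onto a union grid
with an observation mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ProbeGrid",
    "SignalMatrix",
    "NoiseEstimate",
    "InsufficientDataError",
    "compute_mbaf",
    "estimate_sigma",
    "estimate_noise",
    "stack_sequences",
]


class InsufficientDataError(ValueError):
    """Raised when too few observed values are available for an estimate."""


@dataclass(frozen=True)
class ProbeGrid:
    """Ordered probe positions along one chromosome.

    Parameters
    ----------
    chrom
        Chromosome label (e.g. ``"1"`` or ``"chrX"``).
    positions
        Strictly increasing 1-based genomic coordinates (bp).
    names
        Probe identifiers, aligned with ``positions``.
    """

    chrom: str
    positions: np.ndarray
    names: np.ndarray

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        names = np.asarray(self.names, dtype=object)
        if positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if len(names) != len(positions):
            raise ValueError("names and positions must have equal length")
        if len(positions) > 1 and not np.all(np.diff(positions) > 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SignalMatrix:
    """M sequences observed on a shared probe grid with an observation mask.

    ``values[i, j]`` is the signal of sequence ``i`` at grid probe ``j``;
    ``mask[i, j]`` is 1 exactly where that value was observed.  Entries with
    ``mask == 0`` are placeholders and carry no information; the mask, not
    the value, is authoritative.  Matrices built by :func:`stack_sequences`
    have every grid probe observed by at least one sequence (the grid is
    the union of observed positions); row-subset views need not.
    """

    grid: ProbeGrid
    values: np.ndarray
    mask: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))
        if values.shape != mask.shape:
            raise ValueError("values and mask must have the same shape")
        if values.shape[1] != len(self.grid):
            raise ValueError("number of columns must match the grid size")
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("observed (masked-in) values must be finite")
        self.values = values
        self.mask = mask
        if not self.labels:
            self.labels = [f"seq{i}" for i in range(values.shape[0])]
        if len(self.labels) != values.shape[0]:
            raise ValueError("labels must have one entry per sequence")

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    def observed(self, i: int) -> np.ndarray:
        """Observed values of sequence ``i`` in grid order."""
        return self.values[i, self.mask[i]]


@dataclass(frozen=True)
class NoiseEstimate:
    """Per-sequence robust noise level, in signal units."""

    sigma: np.ndarray
    method: str

    def __post_init__(self) -> None:
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sigma < 0):
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "sigma", sigma)


def compute_mbaf(
    baf: np.ndarray, het_band: tuple[float, float] = (0.03, 0.97)
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror BAF around 1/2 and drop apparent homozygotes.

    The two alleles of a SNP are exchangeable, so ``max(b, 1 - b)`` carries
    the same information as ``b`` while turning allelic imbalance into a
    mean shift away from 0.5.  Homozygous probes (BAF pinned near 0 or 1)
    are uninformative about imbalance and are masked out, leaving the
    mirrored signal defined on a coarser grid than the input.

    Parameters
    ----------
    baf
        BAF values in [0, 1]; NaN marks missing probes.
    het_band
        Open interval ``(lo, hi)``; probes whose BAF falls outside
        ``(lo, hi) U (1-hi, 1-lo)`` are treated as homozygous and masked.

    Returns
    -------
    mbaf, mask
        ``mbaf`` has mirrored values in [0.5, 1] where ``mask`` is True and
        NaN elsewhere.
    """
    lo, hi = het_band
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError(f"invalid heterozygote band ({lo}, {hi})")
    baf = np.asarray(baf, dtype=float)
    finite = np.isfinite(baf)
    if np.any((baf[finite] < 0) | (baf[finite] > 1)):
        raise ValueError("BAF values must lie in [0, 1]")
    inside = np.zeros_like(baf, dtype=bool)
    b = baf[finite]
    inside[finite] = ((b > lo) & (b < hi)) | ((b > 1 - hi) & (b < 1 - lo))
    mbaf = np.full_like(baf, np.nan)
    mbaf[inside] = np.maximum(baf[inside], 1.0 - baf[inside])
    return mbaf, inside


def estimate_sigma(y: np.ndarray, method: str = "mad") -> float:
    """Robust noise SD from first differences of consecutive observed values.

    For a piecewise-constant signal with iid noise of variance sigma^2, the
    lag-1 differences Delta_j = y_{j+1} - y_j have variance 2*sigma^2 except
    at the few probes bridging real change points, so
    sigma_hat = dispersion(Delta) / sqrt(2).  The MAD dispersion (scaled to
    be consistent for a Gaussian SD) is robust to those change points; the
    plain standard deviation is available as an alternative.

    Differences are taken between consecutive observed entries, skipping
    missing ones, regardless of the genomic gap between them.
    """
    y = np.asarray(y, dtype=float)
    obs = y[np.isfinite(y)]
    if obs.size < 3:
        raise InsufficientDataError(
            f"need >=3 observed values to estimate sigma, got {obs.size}"
        )
    delta = np.diff(obs)
    if method == "mad":
        disp = stats.median_abs_deviation(delta, scale="normal")
    elif method == "sd":
        disp = float(np.std(delta, ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}; use 'mad' or 'sd'")
    return float(disp) / np.sqrt(2.0)


def estimate_noise(data: SignalMatrix, method: str = "mad") -> NoiseEstimate:
    """Per-sequence :func:`estimate_sigma` over the observed entries."""
    sigma = np.empty(data.M)
    for i in range(data.M):
        sigma[i] = estimate_sigma(data.observed(i), method=method)
    return NoiseEstimate(sigma=sigma, method=method)


def stack_sequences(
    tracks: list[tuple[ProbeGrid, np.ndarray]], labels: list[str] | None = None
) -> SignalMatrix:
    """Align sequences measured at partially overlapping positions.

    The output grid is the sorted union S of all track positions; the mask
    records, per track, which union probes it actually observed.  Values at
    unobserved probes are NaN placeholders excluded from every data term
    downstream.

    All tracks must lie on one chromosome (a CNV never spans two), and no
    track may report the same position twice.
    """
    if not tracks:
        raise ValueError("need at least one track")
    chroms = {grid.chrom for grid, _ in tracks}
    if len(chroms) > 1:
        raise ValueError(f"tracks mix chromosomes: {sorted(chroms)}")
    for grid, vals in tracks:
        if len(np.unique(grid.positions)) != len(grid.positions):
            raise ValueError("duplicate position within one track")
        if len(np.asarray(vals)) != len(grid):
            raise ValueError("track values must match its grid length")

    union_pos = np.unique(np.concatenate([g.positions for g, _ in tracks]))
    name_of: dict[int, str] = {}
    for grid, _ in tracks:
        for pos, name in zip(grid.positions, grid.names):
            name_of.setdefault(int(pos), str(name))
    union_grid = ProbeGrid(
        chrom=next(iter(chroms)),
        positions=union_pos,
        names=np.array([name_of[int(p)] for p in union_pos], dtype=object),
    )

    M, N = len(tracks), len(union_pos)
    values = np.full((M, N), np.nan)
    mask = np.zeros((M, N), dtype=bool)
    for i, (grid, vals) in enumerate(tracks):
        idx = np.searchsorted(union_pos, grid.positions)
        values[i, idx] = np.asarray(vals, dtype=float)
        mask[i, idx] = np.isfinite(np.asarray(vals, dtype=float))
    if not mask.any(axis=0).all():
        # positions contributed only by all-NaN entries: drop them
        keep = mask.any(axis=0)
        union_grid = ProbeGrid(
            chrom=union_grid.chrom,
            positions=union_grid.positions[keep],
            names=union_grid.names[keep],
        )
        values = values[:, keep]
        mask = mask[:, keep]
    return SignalMatrix(grid=union_grid, values=values, mask=mask, labels=labels or [])
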