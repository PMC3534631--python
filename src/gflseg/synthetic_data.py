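"""Synthetic LRR/BAF cohorts with known copy-number truth.

Three generators cover the study designs the segmentation and calling
stages are meant for:

* ``generate_cohort`` — normal samples with short CNVs (a few to a few
  dozen probes) inserted at known places; per-probe LRR is Gaussian around
  the state mean and BAF follows the genotype-cluster mixture with
  Hardy-Weinberg genotype sampling.
* ``generate_tumor_dilution`` — a tumor sample contaminated in silico by a
  fraction ``alpha`` of normal cells: region means interpolate between the
  aberrant and diploid levels, including copy-neutral LOH regions that are
  LRR-invisible but BAF-visible.
* ``generate_pedigree_cohort`` — a group of sequences in which each CNV is
  carried by a random subset of expected size p_share * M, the regime the
  group-fusion penalty targets.

The LRR noise is Gaussian (real array noise has heavier tails and local
waves; detection rates here are therefore an idealized ceiling, not a
reproduction of array benchmarks).  Genotypes are independent across
probes — linkage is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv_calling import StateModel
from .signal_model import ProbeGrid, SignalMatrix

__all__ = [
    "CNVSpec",
    "TumorCNVSpec",
    "NoiseSpec",
    "TruthTable",
    "generate_cohort",
    "generate_tumor_dilution",
    "generate_pedigree_cohort",
    "score_detection",
]


@dataclass(frozen=True)
class CNVSpec:
    """One inserted CNV: 0-based start probe, length, state, carrier rows."""

    start: int
    length: int
    state: int
    carriers: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.length < 1 or self.start < 0:
            raise ValueError("invalid CNV span")
        if self.state == 2 or self.state not in (0, 1, 3, 4):
            raise ValueError("CNV state must be in {0, 1, 3, 4}")
        if not self.carriers:
            raise ValueError("carrier set must be non-empty")


@dataclass(frozen=True)
class TumorCNVSpec:
    """Tumor region with allele-specific copy counts (major, minor).

    Total tumor copy number is major + minor; (2, 0) encodes copy-neutral
    LOH.  ``start`` is a 0-based probe index.
    """

    start: int
    length: int
    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.length < 1 or self.start < 0:
            raise ValueError("invalid region span")
        if self.major < self.minor or self.minor < 0:
            raise ValueError("need major >= minor >= 0")

    @property
    def total(self) -> int:
        return self.major + self.minor


@dataclass
class NoiseSpec:
    """Noise levels for the generators (LRR SD in log2-ratio units)."""

    lrr_sd: float = 0.2
    baf_sd_boundary: float = 0.03
    baf_sd_interior: float = 0.05
    outlier_frac: float = 0.01

    def __post_init__(self) -> None:
        if min(self.lrr_sd, self.baf_sd_boundary, self.baf_sd_interior) <= 0:
            raise ValueError("SDs must be positive")
        if not 0 <= self.outlier_frac < 1:
            raise ValueError("outlier_frac must be in [0, 1)")


@dataclass
class TruthTable:
    """Per-probe true copy number plus the generating region list."""

    cn: np.ndarray  # (M, N) integer copy number
    regions: pd.DataFrame  # sample, start_probe, end_probe (1-based incl), state
    cnloh: np.ndarray | None = None  # (M, N) bool, tumor generator only

    @property
    def is_variant(self) -> np.ndarray:
        var = self.cn != 2
        if self.cnloh is not None:
            var = var | self.cnloh
        return var


def _default_grid(N: int, chrom: str = "1", spacing: int = 1000) -> ProbeGrid:
    positions = np.arange(1, N + 1, dtype=np.int64) * spacing
    names = np.array([f"rs{j}" for j in range(1, N + 1)], dtype=object)
    return ProbeGrid(chrom=chrom, positions=positions, names=names)


def _check_overlap(specs: list[CNVSpec], M: int, N: int) -> None:
    cover: dict[int, list[tuple[int, int]]] = {}
    for spec in specs:
        if spec.start + spec.length > N:
            raise ValueError("CNV extends beyond the grid")
        for i in spec.carriers:
            if not 0 <= i < M:
                raise ValueError(f"carrier {i} outside 0..{M - 1}")
            for s, e in cover.setdefault(i, []):
                if spec.start < e and s < spec.start + spec.length:
                    raise ValueError(f"overlapping CNVs for carrier {i}")
            cover[i].append((spec.start, spec.start + spec.length))


def _draw_baf(
    cn: np.ndarray, model: StateModel, noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """BAF from genotype clusters: B-copies ~ Binomial(cn, p_B) per probe."""
    flat_cn = cn.ravel()
    baf = rng.uniform(0.0, 1.0, size=flat_cn.size)  # CN=0 default: pure noise
    nz = flat_cn > 0
    b = rng.binomial(flat_cn[nz], model.p_b)
    centers = b / flat_cn[nz]
    sds = np.where(
        (centers == 0.0) | (centers == 1.0),
        noise.baf_sd_boundary,
        noise.baf_sd_interior,
    )
    baf[nz] = np.clip(centers + rng.normal(0.0, sds), 0.0, 1.0)
    outlier = rng.uniform(size=flat_cn.size) < noise.outlier_frac
    baf[outlier] = rng.uniform(0.0, 1.0, size=int(outlier.sum()))
    return baf.reshape(cn.shape)


def _regions_frame(specs: list[CNVSpec], labels: list[str]) -> pd.DataFrame:
    rows = [
        {
            "sample": labels[i],
            "start_probe": spec.start + 1,
            "end_probe": spec.start + spec.length,
            "state": spec.state,
        }
        for spec in specs
        for i in spec.carriers
    ]
    cols = ["sample", "start_probe", "end_probe", "state"]
    return pd.DataFrame(rows, columns=cols)


def generate_cohort(
    M: int,
    N: int,
    specs: list[CNVSpec],
    noise: NoiseSpec = NoiseSpec(),
    model: StateModel = StateModel(),
    seed: int | np.random.Generator = 0,
    chrom: str = "1",
) -> tuple[SignalMatrix, SignalMatrix, TruthTable]:
    """Normal-cohort generator: LRR and BAF matrices plus per-probe truth."""
    rng = np.random.default_rng(seed)
    _check_overlap(specs, M, N)
    grid = _default_grid(N, chrom)
    labels = [f"sample{i}" for i in range(M)]

    cn = np.full((M, N), 2, dtype=int)
    for spec in specs:
        for i in spec.carriers:
            cn[i, spec.start : spec.start + spec.length] = spec.state

    means = np.asarray(model.lrr_means)[cn]
    lrr = means + rng.normal(0.0, noise.lrr_sd, size=(M, N))
    baf = _draw_baf(cn, model, noise, rng)

    full = np.ones((M, N), dtype=bool)
    truth = TruthTable(cn=cn, regions=_regions_frame(specs, labels))
    return (
        SignalMatrix(grid=grid, values=lrr, mask=full, labels=list(labels)),
        SignalMatrix(grid=grid, values=baf, mask=full.copy(), labels=list(labels)),
        truth,
    )


def generate_tumor_dilution(
    N: int,
    specs: list[TumorCNVSpec],
    alpha: float,
    noise: NoiseSpec = NoiseSpec(),
    model: StateModel = StateModel(),
    seed: int | np.random.Generator = 0,
    chrom: str = "1",
    lrr_floor: float = -5.0,
) -> tuple[SignalMatrix, SignalMatrix, TruthTable]:
    """One tumor sample diluted with a fraction ``alpha`` of normal cells.

    Per probe, the effective copy number is n_eff = 2*alpha +
    (1-alpha)*c_tumor, giving LRR mean log2(n_eff / 2) (clipped at
    ``lrr_floor``, where arrays saturate) and, for a germline genotype with
    g B alleles and tumor B count b_t, BAF mean
    (alpha*g + (1-alpha)*b_t) / n_eff.  Germline genotypes are
    Hardy-Weinberg at the model's p_B; for heterozygotes the affected
    haplotype is chosen at random per probe (no linkage), so b_t is the
    major or minor count with equal probability.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = _default_grid(N, chrom)

    major = np.ones(N, dtype=int)
    minor = np.ones(N, dtype=int)
    cnloh = np.zeros(N, dtype=bool)
    seen: list[tuple[int, int]] = []
    for spec in specs:
        if spec.start + spec.length > N:
            raise ValueError("region extends beyond the grid")
        for s, e in seen:
            if spec.start < e and s < spec.start + spec.length:
                raise ValueError("overlapping tumor regions")
        seen.append((spec.start, spec.start + spec.length))
        sl = slice(spec.start, spec.start + spec.length)
        major[sl] = spec.major
        minor[sl] = spec.minor
        cnloh[sl] = spec.total == 2 and spec.major != 1

    c_tumor = major + minor
    n_eff = 2.0 * alpha + (1.0 - alpha) * c_tumor
    with np.errstate(divide="ignore"):
        lrr_mean = np.where(n_eff > 0, np.log2(np.maximum(n_eff, 1e-300) / 2.0), lrr_floor)
    lrr_mean = np.maximum(lrr_mean, lrr_floor)
    lrr = lrr_mean + rng.normal(0.0, noise.lrr_sd, size=N)

    g = rng.binomial(2, model.p_b, size=N)  # germline B-allele count
    b_t = np.empty(N, dtype=float)
    hom0, het, hom2 = g == 0, g == 1, g == 2
    b_t[hom0] = 0.0
    b_t[hom2] = c_tumor[hom2]
    pick_major = rng.uniform(size=N) < 0.5
    b_t[het] = np.where(pick_major[het], major[het], minor[het])

    num = alpha * g + (1.0 - alpha) * b_t
    baf_mean = np.where(n_eff > 0, num / np.maximum(n_eff, 1e-12), np.nan)
    sds = np.where(
        (baf_mean <= 0.0) | (baf_mean >= 1.0),
        noise.baf_sd_boundary,
        noise.baf_sd_interior,
    )
    baf = np.clip(baf_mean + rng.normal(0.0, sds), 0.0, 1.0)
    baf[~np.isfinite(baf_mean)] = rng.uniform(size=int(np.sum(~np.isfinite(baf_mean))))
    outlier = rng.uniform(size=N) < noise.outlier_frac
    baf[outlier] = rng.uniform(size=int(outlier.sum()))

    # truth records the tumor state; contamination attenuates the signal but
    # does not change what the region is
    cn_truth = c_tumor[None, :].copy()
    regions = pd.DataFrame(
        [
            {
                "sample": "tumor",
                "start_probe": spec.start + 1,
                "end_probe": spec.start + spec.length,
                "state": spec.total,
            }
            for spec in specs
        ],
        columns=["sample", "start_probe", "end_probe", "state"],
    )
    truth = TruthTable(cn=cn_truth, regions=regions, cnloh=cnloh[None, :])
    full = np.ones((1, N), dtype=bool)
    return (
        SignalMatrix(grid=grid, values=lrr[None, :], mask=full, labels=["tumor"]),
        SignalMatrix(grid=grid, values=baf[None, :], mask=full.copy(), labels=["tumor"]),
        truth,
    )


def generate_pedigree_cohort(
    M: int,
    N: int,
    p_share: float,
    specs: list[CNVSpec],
    noise: NoiseSpec = NoiseSpec(),
    model: StateModel = StateModel(),
    seed: int | np.random.Generator = 0,
    chrom: str = "1",
) -> tuple[SignalMatrix, SignalMatrix, TruthTable]:
    """Cohort in which each CNV is carried by a random ~p_share fraction.

    Carrier sets are redrawn per spec: each of the M sequences carries the
    CNV independently with probability ``p_share``, with at least one
    carrier forced (an event nobody carries is not a CNV of the cohort).
    The ``carriers`` field of the input specs is ignored.
    """
    if not 0.0 < p_share <= 1.0:
        raise ValueError("p_share must be in (0, 1]")
    rng = np.random.default_rng(seed)
    drawn: list[CNVSpec] = []
    for spec in specs:
        carriers = np.nonzero(rng.uniform(size=M) < p_share)[0]
        if carriers.size == 0:
            carriers = np.array([rng.integers(M)])
        drawn.append(
            CNVSpec(
                start=spec.start,
                length=spec.length,
                state=spec.state,
                carriers=tuple(int(i) for i in carriers),
            )
        )
    return generate_cohort(M, N, drawn, noise=noise, model=model, seed=rng, chrom=chrom)


_LENGTH_CLASSES = ((1, 5), (6, 10), (11, 20), (21, 30), (31, 40), (41, 10**9))


def _calls_to_matrix(calls: pd.DataFrame, labels: list[str], N: int) -> np.ndarray:
    cn = np.full((len(labels), N), 2, dtype=int)
    index = {lab: i for i, lab in enumerate(labels)}
    for _, row in calls.iterrows():
        if row["sample"] not in index:
            raise ValueError(f"unknown sample {row['sample']!r} in calls")
        i = index[row["sample"]]
        cn[i, int(row["start_probe"]) - 1 : int(row["end_probe"])] = int(row["state"])
    return cn


def score_detection(
    truth: TruthTable, calls: pd.DataFrame, labels: list[str] | None = None
) -> pd.DataFrame:
    """Per-probe true-positive rate and false-discovery rate of CNV calls.

    ``calls`` needs columns sample, start_probe, end_probe (1-based
    inclusive), state; probes not covered by any call are diploid.  A truth
    probe counts as detected when it is called with a variant of the same
    direction (loss/gain).  FDR is the fraction of variant-called probes
    whose truth is diploid.  Rates are reported overall and broken out by
    variant type and CNV length class; when no probes are called variant
    the FDR is reported as 0 with ``defined = False``.
    """
    M, N = truth.cn.shape
    if labels is None:
        labels = sorted(set(truth.regions["sample"])) or [f"sample{i}" for i in range(M)]
        if len(labels) != M:
            labels = [f"sample{i}" for i in range(M)]
    called = _calls_to_matrix(calls, labels, N)

    true_var = truth.cn != 2
    called_var = called != 2
    same_dir = ((truth.cn < 2) & (called < 2)) | ((truth.cn > 2) & (called > 2))

    rows = []

    def add_row(kind: str, length_class: str, tmask: np.ndarray, cmask: np.ndarray):
        n_true = int(tmask.sum())
        n_called = int(cmask.sum())
        tp = int((tmask & same_dir).sum())
        fp = int((cmask & ~true_var).sum())
        rows.append(
            {
                "type": kind,
                "length_class": length_class,
                "n_true_probes": n_true,
                "n_called_probes": n_called,
                "tpr": 100.0 * tp / n_true if n_true else np.nan,
                "fdr": 100.0 * fp / n_called if n_called else 0.0,
                "fdr_defined": n_called > 0,
            }
        )

    add_row("any", "all", true_var, called_var)
    add_row("deletion", "all", truth.cn < 2, called < 2)
    add_row("duplication", "all", truth.cn > 2, called > 2)

    index = {lab: i for i, lab in enumerate(labels)}
    for lo, hi in _LENGTH_CLASSES:
        tmask = np.zeros_like(true_var)
        for _, reg in truth.regions.iterrows():
            length = int(reg["end_probe"]) - int(reg["start_probe"]) + 1
            if lo <= length <= hi and reg["sample"] in index:
                i = index[reg["sample"]]
                tmask[i, int(reg["start_probe"]) - 1 : int(reg["end_probe"])] = True
        if tmask.any():
            label = f"{lo}-{hi}" if hi < 10**9 else f">={lo}"
            add_row("any", label, tmask, called_var & tmask)
    return pd.DataFrame(rows)
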