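"""End-to-end pipelines binding the model stages together.

A chromosome at a time (a CNV never spans two chromosomes), the segment
pipeline runs: noise estimation -> guideline penalties -> smoothed GFL fit
-> jump extraction -> hard thresholding -> segment table.  Two analysis
modes exist:

* ``individual`` — each sample is fit on its own.  With ``signals="both"``
  the sample's LRR and (centered) mBAF rows are stacked on their union grid
  and fused with p = 1 (the two signals describe the same genome, so their
  change points must coincide); retained change points from the two rows
  are unioned into one finer segmentation.
* ``joint`` — all samples are fit together with a user-supplied sharing
  proportion p, which moves penalty weight from within-sequence fusion to
  the cross-sequence group term.

mBAF rows are centered at 0.5 (their diploid level) before fitting so that
the sparsity penalty shrinks every signal toward its own baseline.
Calling is always per sample, using the segment's raw LRR and BAF values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cnv_calling import CallingConfig, StateModel, call_segment
from .gfl_solver import fit_gfl
from .segmentation import (
    JumpSet,
    ThresholdConfig,
    extract_jumps,
    jumps_to_segments,
    mbic_threshold,
    ruler_threshold,
    union_changepoints,
)
from .signal_model import (
    SignalMatrix,
    compute_mbaf,
    estimate_noise,
    stack_sequences,
)
from .tuning import TuningInputs, default_penalties

__all__ = ["SegmentOptions", "segment_chromosome", "call_chromosome"]

_JUMP_FLOOR_FACTOR = 1e-6


@dataclass
class SegmentOptions:
    """Knobs of the segmentation pipeline (see module docstring)."""

    mode: str = "individual"
    signals: str = "lrr"
    p: float = 0.0
    c1: float = 0.1
    c2: float = 1.0
    c3: float = 1.0
    epsilon: float = 1e-8
    tol: float = 1e-6
    max_iter: int = 500
    sigma_method: str = "mad"
    threshold: ThresholdConfig = None
    het_band: tuple[float, float] = (0.03, 0.97)

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "joint"):
            raise ValueError("mode must be 'individual' or 'joint'")
        if self.signals not in ("lrr", "mbaf", "both"):
            raise ValueError("signals must be 'lrr', 'mbaf' or 'both'")
        if self.threshold is None:
            self.threshold = ThresholdConfig()


def _threshold(
    jumps: JumpSet, data: SignalMatrix, sigma: np.ndarray, opts: SegmentOptions
) -> JumpSet:
    if opts.threshold.method == "ruler":
        return ruler_threshold(jumps, sigma, opts.threshold)
    indices, sizes = [], []
    for i in range(jumps.M):
        # mBIC operates on observed values; candidate grid indices are
        # mapped to positions in the observed subsequence and back
        obs_idx = np.nonzero(data.mask[i])[0]
        cand_obs = np.searchsorted(obs_idx, jumps.indices[i])
        valid = (cand_obs > 0) & (cand_obs < len(obs_idx))
        kept_obs = mbic_threshold(
            data.observed(i), cand_obs[valid], jumps.sizes[i][valid]
        )
        keep = np.isin(cand_obs, kept_obs) & valid
        indices.append(jumps.indices[i][keep])
        sizes.append(jumps.sizes[i][keep])
    return JumpSet(indices=indices, sizes=sizes, n_probes=jumps.n_probes)


def _fit_and_threshold(
    data: SignalMatrix, p: float, opts: SegmentOptions
) -> tuple[JumpSet, np.ndarray, object]:
    noise = estimate_noise(data, method=opts.sigma_method)
    sigma = np.maximum(noise.sigma, 1e-12)
    tune = TuningInputs(
        sigma=sigma, N=data.N, M=data.M, p=p, c1=opts.c1, c2=opts.c2, c3=opts.c3
    )
    cfg = default_penalties(
        tune, epsilon=opts.epsilon, tol=opts.tol, max_iter=opts.max_iter
    )
    result = fit_gfl(data, cfg)
    lax = extract_jumps(result.beta, floor=_JUMP_FLOOR_FACTOR * sigma)
    kept = _threshold(lax, data, sigma, opts)
    return kept, sigma, result


def _sample_tracks(
    lrr: SignalMatrix, baf: SignalMatrix | None, i: int, opts: SegmentOptions
) -> SignalMatrix:
    """One sample's fitting matrix: LRR and/or centered mBAF on a union grid."""
    tracks, labels = [], []
    lrr_vals = np.where(lrr.mask[i], lrr.values[i], np.nan)
    if opts.signals in ("lrr", "both"):
        tracks.append((lrr.grid, lrr_vals))
        labels.append(f"{lrr.labels[i]}:lrr")
    if opts.signals in ("mbaf", "both"):
        if baf is None:
            raise ValueError("signals mode requires BAF data")
        bvals = np.where(baf.mask[i], baf.values[i], np.nan)
        mbaf, _ = compute_mbaf(bvals, het_band=opts.het_band)
        tracks.append((baf.grid, mbaf - 0.5))
        labels.append(f"{lrr.labels[i]}:mbaf"
                      if opts.signals == "both" else f"{baf.labels[i]}:mbaf")
    return stack_sequences(tracks, labels=labels)


def segment_chromosome(
    lrr: SignalMatrix,
    baf: SignalMatrix | None = None,
    opts: SegmentOptions = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment one chromosome; returns (segment table, retained-jump audit).

    The segment table partitions the probe range per sample, with means
    recomputed from observed LRR; the audit table lists every retained
    jump with its size and the cutoff it cleared.
    """
    opts = opts or SegmentOptions()
    segments_frames, audit_rows = [], []

    if opts.mode == "individual":
        fits = []
        for i in range(lrr.M):
            data = _sample_tracks(lrr, baf, i, opts)
            p = 1.0 if data.M > 1 else 0.0  # one genome: signals share jumps
            kept, sigma, _ = _fit_and_threshold(data, p, opts)
            fits.append((lrr.labels[i], data, kept, sigma))
    else:
        tracks, labels, row_owner = [], [], []
        for i in range(lrr.M):
            sub = _sample_tracks(lrr, baf, i, opts)
            for r in range(sub.M):
                tracks.append((sub.grid, np.where(sub.mask[r], sub.values[r], np.nan)))
                labels.append(sub.labels[r])
                row_owner.append(i)
        data = stack_sequences(tracks, labels=labels)
        kept_all, sigma_all, _ = _fit_and_threshold(data, opts.p, opts)
        fits = []
        for i in range(lrr.M):
            rows = [r for r, owner in enumerate(row_owner) if owner == i]
            sub_kept = JumpSet(
                indices=[kept_all.indices[r] for r in rows],
                sizes=[kept_all.sizes[r] for r in rows],
                n_probes=kept_all.n_probes,
            )
            sub_data = SignalMatrix(
                grid=data.grid,
                values=data.values[rows],
                mask=data.mask[rows],
                labels=[labels[r] for r in rows],
            )
            fits.append((lrr.labels[i], sub_data, sub_kept, sigma_all[rows]))

    for sample, data, kept, sigma in fits:
        merged = union_changepoints([kept]) if data.M > 1 else kept
        # segments are reported on the sample's LRR track when present,
        # otherwise on the first fitted track
        lrr_rows = [r for r, lab in enumerate(data.labels) if lab.endswith(":lrr")]
        r0 = lrr_rows[0] if lrr_rows else 0
        one = SignalMatrix(
            grid=data.grid,
            values=data.values[[r0]],
            mask=data.mask[[r0]],
            labels=[sample],
        )
        one_jumps = JumpSet(
            indices=[merged.indices[0]], sizes=[merged.sizes[0]], n_probes=merged.n_probes
        )
        segments_frames.append(jumps_to_segments(one_jumps, one))
        for r in range(data.M):
            for j, s in zip(kept.indices[r], kept.sizes[r]):
                audit_rows.append(
                    {
                        "sample": sample,
                        "signal": data.labels[r],
                        "chrom": data.grid.chrom,
                        "probe_index": int(j) + 1,
                        "position": int(data.grid.positions[j]),
                        "jump": float(s),
                        "sigma": float(sigma[r]),
                    }
                )
    segments = pd.concat(segments_frames, ignore_index=True)
    audit = pd.DataFrame(
        audit_rows,
        columns=["sample", "signal", "chrom", "probe_index", "position", "jump", "sigma"],
    )
    return segments, audit


def call_chromosome(
    segments: pd.DataFrame,
    lrr: SignalMatrix,
    baf: SignalMatrix | None,
    model: StateModel = None,
    cfg: CallingConfig = None,
    sigma_method: str = "mad",
) -> pd.DataFrame:
    """Apply the five-state caller to every segment of every sample.

    The state model's LRR noise SD is replaced by each sample's own robust
    estimate, which also scales the r2 mean-shift guard.  Every input
    segment yields one output row, accepted or not.
    """
    model = model or StateModel()
    cfg = cfg or CallingConfig()
    noise = estimate_noise(lrr, method=sigma_method)
    index = {lab: i for i, lab in enumerate(lrr.labels)}
    rows = []
    for _, seg in segments.iterrows():
        sample = seg["sample"]
        if sample not in index:
            raise ValueError(f"segment references unknown sample {sample!r}")
        i = index[sample]
        s, e = int(seg["start_probe"]) - 1, int(seg["end_probe"])
        y = lrr.values[i, s:e][lrr.mask[i, s:e]]
        x = None
        if baf is not None:
            # align BAF probes falling inside the segment's genomic span
            lo = lrr.grid.positions[s]
            hi = lrr.grid.positions[e - 1]
            sel = (baf.grid.positions >= lo) & (baf.grid.positions <= hi)
            xi = index.get(sample, i) if baf.M == lrr.M else 0
            x = baf.values[xi, sel][baf.mask[xi, sel]]
        sigma_i = max(float(noise.sigma[i]), 1e-12)
        sample_model = replace(model, lrr_sd=sigma_i)
        if y.size == 0 and (x is None or x.size == 0):
            rows.append(
                {
                    "sample": sample,
                    "chrom": seg["chrom"],
                    "start_probe": int(seg["start_probe"]),
                    "end_probe": int(seg["end_probe"]),
                    "n_probes": 0,
                    "state": 2,
                    "lr": np.nan,
                    "lrr_mean": np.nan,
                    "accepted": False,
                    "reason": "no_data",
                }
            )
            continue
        call = call_segment(x, y, sample_model, cfg, sigma=sigma_i)
        best_lr = max(call.lr.values()) if call.lr else np.nan
        rows.append(
            {
                "sample": sample,
                "chrom": seg["chrom"],
                "start_probe": int(seg["start_probe"]),
                "end_probe": int(seg["end_probe"]),
                "n_probes": int(seg["n_probes"]),
                "state": call.state,
                "lr": best_lr,
                "lrr_mean": call.lrr_mean,
                "accepted": call.accepted,
                "reason": call.reason,
            }
        )
    return pd.DataFrame(rows)
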