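"""Round-trip file I/O for signal tables, segments, calls and truth.

Signal files follow the de-facto standard split-signal export of
genotyping arrays: tab-delimited with header columns ``Name``, ``Chr``,
``Position``, ``<sample>.Log R Ratio`` and ``<sample>.B Allele Freq``,
positions 1-based.  Segment and call tables are exported with BED-style
0-based half-open genomic intervals; probe indices inside the library stay
1-based inclusive, and :func:`to_bed_interval` is the single conversion
point between the two conventions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signal_model import ProbeGrid, SignalMatrix

__all__ = [
    "read_signal_table",
    "write_signal_table",
    "signal_frames_to_matrices",
    "to_bed_interval",
    "write_segments",
    "read_segments",
    "write_calls",
    "write_truth_regions",
    "read_truth_regions",
    "load_config",
]

LRR_SUFFIX = ".Log R Ratio"
BAF_SUFFIX = ".B Allele Freq"


def read_signal_table(path: str | Path) -> tuple[list[str], pd.DataFrame]:
    """Read a split-signal file; returns (sample names, tidy frame).

    The frame has columns Name, Chr, Position plus ``<sample>.Log R Ratio``
    / ``<sample>.B Allele Freq`` pairs, sorted by (Chr, Position).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"Name", "Chr", "Position"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {required - set(df.columns)}")
    samples = sorted(
        {c[: -len(LRR_SUFFIX)] for c in df.columns if c.endswith(LRR_SUFFIX)}
    )
    if not samples:
        raise ValueError(f"{path}: no '<sample>{LRR_SUFFIX}' columns found")
    df["Chr"] = df["Chr"].astype(str)
    return samples, df.sort_values(["Chr", "Position"], kind="stable").reset_index(drop=True)


def write_signal_table(
    path: str | Path,
    grid: ProbeGrid,
    sample: str,
    lrr: np.ndarray,
    baf: np.ndarray,
) -> None:
    """Write one sample's LRR/BAF on a grid in the split-signal format."""
    df = pd.DataFrame(
        {
            "Name": grid.names,
            "Chr": grid.chrom,
            "Position": grid.positions,
            f"{sample}{LRR_SUFFIX}": np.asarray(lrr, dtype=float),
            f"{sample}{BAF_SUFFIX}": np.asarray(baf, dtype=float),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def signal_frames_to_matrices(
    samples: list[str], df: pd.DataFrame
) -> dict[str, tuple[ProbeGrid, pd.DataFrame]]:
    """Split a tidy signal frame per chromosome, building probe grids."""
    out: dict[str, tuple[ProbeGrid, pd.DataFrame]] = {}
    for chrom, sub in df.groupby("Chr", sort=True):
        sub = sub.sort_values("Position", kind="stable")
        grid = ProbeGrid(
            chrom=str(chrom),
            positions=sub["Position"].to_numpy(np.int64),
            names=sub["Name"].to_numpy(object),
        )
        out[str(chrom)] = (grid, sub.reset_index(drop=True))
    return out


def to_bed_interval(
    grid_positions: np.ndarray, start_probe: int, end_probe: int
) -> tuple[int, int]:
    """Map 1-based inclusive probe indices to a 0-based half-open bp span."""
    start_bp = int(grid_positions[start_probe - 1]) - 1
    end_bp = int(grid_positions[end_probe - 1])
    return start_bp, end_bp


_SEGMENT_COLS = ["sample", "chrom", "start", "end", "start_probe", "end_probe", "n_probes", "mean"]


def write_segments(path: str | Path, segments: pd.DataFrame, grid_positions_by_chrom: dict[str, np.ndarray], header_lines: list[str] | None = None) -> None:
    """Write a segment table with BED-style bp intervals."""
    rows = []
    for _, seg in segments.iterrows():
        pos = grid_positions_by_chrom[str(seg["chrom"])]
        start, end = to_bed_interval(pos, int(seg["start_probe"]), int(seg["end_probe"]))
        rows.append(
            {
                "sample": seg["sample"],
                "chrom": seg["chrom"],
                "start": start,
                "end": end,
                "start_probe": int(seg["start_probe"]),
                "end_probe": int(seg["end_probe"]),
                "n_probes": int(seg["n_probes"]),
                "mean": seg["mean"],
            }
        )
    out = pd.DataFrame(rows, columns=_SEGMENT_COLS)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_segments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def write_calls(path: str | Path, calls: pd.DataFrame, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        calls.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_truth_regions(path: str | Path, regions: pd.DataFrame, grid: ProbeGrid) -> None:
    """Write the generating truth regions with BED-style intervals."""
    rows = []
    for _, reg in regions.iterrows():
        start, end = to_bed_interval(grid.positions, int(reg["start_probe"]), int(reg["end_probe"]))
        rows.append(
            {
                "sample": reg["sample"],
                "chrom": grid.chrom,
                "start": start,
                "end": end,
                "start_probe": int(reg["start_probe"]),
                "end_probe": int(reg["end_probe"]),
                "state": int(reg["state"]),
            }
        )
    pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "start_probe", "end_probe", "state"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_regions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
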