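"""Readers and writers for the plain-text genomics formats the pipeline uses.

All coordinates are 0-based half-open (BED convention) in memory and on disk.
Gzip transparency comes for free from pandas/numpy text IO where applicable.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import BinGrid, CoverageTrack

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed_fragments",
    "write_bed_fragments",
    "read_bed_intervals",
    "read_bam_fragments",
    "write_bedgraph",
    "read_bedgraph",
    "write_bigwig",
]


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str, "size": np.int64})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{int(size)}\n")


def _open_text(path, mode):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed_fragments(path) -> pd.DataFrame:
    """Read BED3/BED6 into a fragment DataFrame (strand kept when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns, got {ncol}")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["chrom"] = out["chrom"].astype(str)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if ncol >= 6:
        out["strand"] = df.iloc[:, 5].astype(str)
    return out


def write_bed_fragments(fragments: pd.DataFrame, path) -> None:
    """Write fragments as 3-column BED (plus strand as BED6 when present)."""
    with _open_text(path, "wt") as fh:
        if "strand" in fragments.columns:
            for row in fragments.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t{row.strand}\n")
        else:
            for row in fragments.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def read_bed_intervals(path, name_column: bool = True) -> pd.DataFrame:
    """Read labeled intervals (e.g., SEGWAY states, CpG islands) from BED.

    Returns columns chrom, start, end and, when the file has a 4th column and
    ``name_column`` is true, ``name`` (the state label / feature name).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["chrom"] = out["chrom"].astype(str)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if name_column and df.shape[1] >= 4:
        out["name"] = df.iloc[:, 3].astype(str)
    return out


def read_bam_fragments(path, mapq: int | None = None) -> pd.DataFrame:
    """Fragments from a coordinate-sorted SAM/BAM: proper pairs → insert intervals.

    Each properly paired, primary, forward-of-pair alignment contributes one
    fragment [start, start + |tlen|). An optional MAPQ threshold is exposed but
    off by default.
    """
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    rows = []
    with pysam.AlignmentFile(str(path), mode) as af:
        for aln in af:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or not aln.is_proper_pair
                or aln.is_reverse  # count each pair once, from the plus-strand mate
                or aln.template_length <= 0
            ):
                continue
            if mapq is not None and aln.mapping_quality < mapq:
                continue
            rows.append((aln.reference_name, aln.reference_start,
                         aln.reference_start + aln.template_length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
        {"chrom": str, "start": np.int64, "end": np.int64}
    )


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph at fixed bin step (zero bins included)."""
    w = track.grid.bin_width
    with _open_text(path, "wt") as fh:
        for chrom in track.grid.chroms:
            size = int(track.grid.chrom_sizes[chrom])
            v = track.values[chrom]
            for i, val in enumerate(v):
                end = min((i + 1) * w, size)
                fh.write(f"{chrom}\t{i * w}\t{end}\t{val:.6g}\n")


def read_bedgraph(path, grid: BinGrid) -> CoverageTrack:
    """Read a fixed-step bedGraph produced by :func:`write_bedgraph`."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float})
    track = CoverageTrack.zeros(grid)
    w = grid.bin_width
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in grid")
        track.values[chrom][sub["start"].to_numpy() // w] = sub["value"].to_numpy()
    return track


def write_bigwig(track: CoverageTrack, path) -> None:
    """Write a track as bigWig (requires the optional pyBigWig dependency)."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("bigWig output requires pyBigWig; bedGraph output "
                          "is always available via write_bedgraph") from exc
    w = track.grid.bin_width
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(c, int(track.grid.chrom_sizes[c])) for c in track.grid.chroms])
    for chrom in track.grid.chroms:
        size = int(track.grid.chrom_sizes[chrom])
        v = track.values[chrom]
        starts = np.arange(len(v), dtype=np.int64) * w
        ends = np.minimum(starts + w, size)
        bw.addEntries([chrom] * len(v), starts.tolist(),
                      ends=ends.tolist(), values=v.astype(float).tolist())
    bw.close()
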