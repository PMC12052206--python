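"""Binned, normalized genome-wide signal tracks from aligned fragments.

The unit of input is the *fragment*: a 0-based half-open genomic interval on a
named chromosome, typically the insert implied by a properly paired read pair
(CUT&RUN, CUT&Tag) or a single-end read extended to the expected fragment
length (ChIP-seq). Fragments are carried as pandas DataFrames with columns
``chrom``, ``start``, ``end`` (and optionally ``strand``).

Coverage is accumulated on a fixed-width bin grid (100 bp by default): every
fragment adds the sample's normalization factor to each bin it overlaps by at
least 1 bp. Two normalization modes are supported:

* spike-in — factor ``10000 / (fragments mapping to the exogenous genome)``,
  which makes samples with different global target occupancy comparable;
* depth — factor ``2.8e9 / (total mapped reads)``, a plain sequencing-depth
  rescaling for experiments without a spike-in.

Tracks can then be smoothed with a running average spanning ±1,000 bp around
each bin and summed across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BinGrid",
    "CoverageTrack",
    "DEFAULT_BIN_WIDTH",
    "SPIKE_IN_SCALE",
    "DEPTH_SCALE",
    "fragments_frame",
    "filter_fragments",
    "dedup_fragments",
    "extend_single_end",
    "spike_in_factor",
    "depth_factor",
    "bin_coverage",
    "smooth_running_average",
    "combine_replicates",
]

DEFAULT_BIN_WIDTH = 100
#: Numerator of the spike-in normalization factor (an arbitrary scale constant).
SPIKE_IN_SCALE = 10_000
#: Numerator of the depth normalization factor, of the order of the mappable
#: genome size in bp.
DEPTH_SCALE = 2_800_000_000

FRAGMENT_COLUMNS = ("chrom", "start", "end")


def fragments_frame(records: Iterable[tuple], strand: bool = False) -> pd.DataFrame:
    """Build a fragment DataFrame from (chrom, start, end[, strand]) tuples."""
    cols = list(FRAGMENT_COLUMNS) + (["strand"] if strand else [])
    df = pd.DataFrame.from_records(list(records), columns=cols)
    if len(df) == 0:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64)})
        if strand:
            df["strand"] = pd.Series(dtype=str)
        return df
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width binning of a genome given per-chromosome lengths.

    The last bin of each chromosome may be partial. Chromosome order is the
    insertion order of ``chrom_sizes`` and is preserved in all outputs.
    """

    chrom_sizes: Mapping[str, int]
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    def n_bins(self, chrom: str) -> int:
        return -(-int(self.chrom_sizes[chrom]) // self.bin_width)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chroms)

    def bin_start(self, chrom: str, index: int) -> int:
        return index * self.bin_width

    def bin_end(self, chrom: str, index: int) -> int:
        return min((index + 1) * self.bin_width, int(self.chrom_sizes[chrom]))


@dataclass(eq=False)
class CoverageTrack:
    """Per-bin normalized signal on a :class:`BinGrid`.

    ``values`` maps chromosome name to a float array of length
    ``grid.n_bins(chrom)``. ``norm_factor`` records the per-fragment increment
    used when the track was built; ``smoothed`` guards against accidental
    double smoothing.
    """

    grid: BinGrid
    values: dict[str, np.ndarray]
    norm_factor: float = 1.0
    smoothed: bool = False
    sample: str = ""

    def __post_init__(self) -> None:
        for chrom in self.grid.chroms:
            if chrom not in self.values:
                raise ValueError(f"track missing chromosome {chrom!r}")
            n = self.grid.n_bins(chrom)
            if len(self.values[chrom]) != n:
                raise ValueError(
                    f"track for {chrom!r} has {len(self.values[chrom])} bins, expected {n}"
                )

    def all_values(self) -> np.ndarray:
        """Genome-wide bin values as one flat array (chromosome order)."""
        return np.concatenate([self.values[c] for c in self.grid.chroms])

    def copy(self) -> "CoverageTrack":
        return replace(self, values={c: v.copy() for c, v in self.values.items()})

    @classmethod
    def zeros(cls, grid: BinGrid, **kwargs) -> "CoverageTrack":
        vals = {c: np.zeros(grid.n_bins(c)) for c in grid.chroms}
        return cls(grid=grid, values=vals, **kwargs)

    def allclose(self, other: "CoverageTrack", rtol: float = 1e-9, atol: float = 0.0) -> bool:
        if self.grid.chroms != other.grid.chroms:
            return False
        return all(
            np.allclose(self.values[c], other.values[c], rtol=rtol, atol=atol)
            for c in self.grid.chroms
        )


# ---------------------------------------------------------------------------
# Fragment-level operations
# ---------------------------------------------------------------------------

def filter_fragments(fragments: pd.DataFrame, min_len: int, max_len: int) -> pd.DataFrame:
    """Keep fragments with ``min_len <= end - start <= max_len`` (both inclusive).

    The retention windows in routine use are 120–500 bp for CUT&RUN and
    120–1000 bp for CUT&Tag.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    length = fragments["end"] - fragments["start"]
    return fragments.loc[(length >= min_len) & (length <= max_len)].reset_index(drop=True)


def dedup_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    """Drop fragments sharing (chrom, start, end) with an earlier one.

    Exact-coordinate duplicates are the signature of PCR duplication in
    fragment-level data; the first occurrence is kept and input order is
    preserved.
    """
    return fragments.drop_duplicates(subset=["chrom", "start", "end"], keep="first").reset_index(
        drop=True
    )


def extend_single_end(
    reads: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    extension: int = 250,
) -> pd.DataFrame:
    """Extend single-end reads from their 5′ end to a fixed fragment length.

    A plus-strand read starting at ``s`` becomes ``[s, s + extension)``; a
    minus-strand read ending at ``e`` becomes ``[e - extension, e)``. Results
    are clipped to chromosome bounds. Used for legacy single-end ChIP-seq
    where the sequenced read is much shorter than the sonicated fragment.
    """
    if "strand" not in reads.columns:
        raise ValueError("extend_single_end requires a 'strand' column (+/-)")
    bad = ~reads["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unrecognized strand values: {sorted(reads.loc[bad, 'strand'].unique())}")
    out = reads.copy()
    plus = out["strand"] == "+"
    out.loc[plus, "end"] = out.loc[plus, "start"] + extension
    out.loc[~plus, "start"] = out.loc[~plus, "end"] - extension
    sizes = out["chrom"].map(dict(chrom_sizes))
    if sizes.isna().any():
        missing = sorted(out.loc[sizes.isna(), "chrom"].unique())
        raise ValueError(f"reads on chromosomes absent from chrom_sizes: {missing}")
    out["start"] = np.maximum(out["start"], 0)
    out["end"] = np.minimum(out["end"], sizes.astype(np.int64))
    return out


# ---------------------------------------------------------------------------
# Normalization factors
# ---------------------------------------------------------------------------

def spike_in_factor(n_spike_fragments: int) -> float:
    """Spike-in normalization factor ``10000 / n_spike_fragments``."""
    if n_spike_fragments <= 0:
        raise ValueError("cannot spike-in normalize: no fragments mapped to the spike-in genome")
    return SPIKE_IN_SCALE / n_spike_fragments


def depth_factor(n_mapped: int) -> float:
    """Depth normalization factor ``2.8e9 / n_mapped``."""
    if n_mapped <= 0:
        raise ValueError("cannot depth normalize: zero mapped reads")
    return DEPTH_SCALE / n_mapped


# ---------------------------------------------------------------------------
# Track construction
# ---------------------------------------------------------------------------

def bin_coverage(
    fragments: pd.DataFrame,
    grid: BinGrid,
    factor: float = 1.0,
    midpoint: bool = False,
    sample: str = "",
) -> CoverageTrack:
    """Accumulate fragments on the bin grid, scaled by ``factor``.

    By default each fragment adds ``factor`` to every bin it overlaps by at
    least 1 bp. With ``midpoint=True`` each fragment is assigned to the single
    bin containing its midpoint instead (non-default; broad-domain analysis
    uses overlap counting).
    """
    if factor <= 0:
        raise ValueError("norm factor must be positive")
    track = CoverageTrack.zeros(grid, norm_factor=factor, sample=sample)
    if len(fragments) == 0:
        return track
    known = set(grid.chroms)
    unknown = set(fragments["chrom"].unique()) - known
    if unknown:
        raise ValueError(f"fragments on chromosome(s) not in the grid: {sorted(unknown)}")
    w = grid.bin_width
    for chrom, sub in fragments.groupby("chrom", sort=False, observed=True):
        n = grid.n_bins(chrom)
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        if (starts < 0).any() or (ends > int(grid.chrom_sizes[chrom])).any():
            raise ValueError(f"fragment outside chromosome bounds on {chrom!r}")
        if midpoint:
            mid = (starts + ends) // 2
            b = np.minimum(mid // w, n - 1)
            counts = np.bincount(b, minlength=n)
            track.values[chrom] += factor * counts
        else:
            b0 = starts // w
            b1 = np.minimum((ends - 1) // w, n - 1) + 1  # exclusive bin end
            diff = np.zeros(n + 1, dtype=np.int64)
            np.add.at(diff, b0, 1)
            np.add.at(diff, b1, -1)
            # integer counts first, one float multiply after: bins no fragment
            # touches stay exactly zero and c-fold replication cancels exactly
            track.values[chrom] += factor * np.cumsum(diff[:-1])
    return track


def smooth_running_average(track: CoverageTrack, half_span: int = 1000) -> CoverageTrack:
    """Running-average smoothing spanning ±``half_span`` bp around each bin.

    Each bin becomes the mean of itself and the flanking bins within
    ``half_span`` on the same chromosome; at chromosome ends the window is
    truncated and the mean taken over the bins that exist (no zero padding,
    so flat signal stays flat at the edges).
    """
    if track.smoothed:
        raise ValueError("track is already smoothed; refusing to smooth twice")
    if half_span % track.grid.bin_width != 0:
        raise ValueError("half_span must be a multiple of the bin width")
    k = half_span // track.grid.bin_width
    out = track.copy()
    out.smoothed = True
    if k == 0:
        return out
    kernel = np.ones(2 * k + 1)
    for chrom in track.grid.chroms:
        v = track.values[chrom]
        sums = np.convolve(v, kernel, mode="same")
        counts = np.convolve(np.ones_like(v), kernel, mode="same")
        out.values[chrom] = sums / counts
    return out


def combine_replicates(tracks: Iterable[CoverageTrack]) -> CoverageTrack:
    """Per-bin sum of replicate tracks (already individually normalized)."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks to combine")
    first = tracks[0]
    for t in tracks[1:]:
        if t.grid.chroms != first.grid.chroms or t.grid.bin_width != first.grid.bin_width or any(
            t.grid.chrom_sizes[c] != first.grid.chrom_sizes[c] for c in first.grid.chroms
        ):
            raise ValueError("cannot combine tracks on different grids")
        if t.smoothed != first.smoothed:
            raise ValueError("cannot combine smoothed with unsmoothed tracks")
    out = first.copy()
    out.sample = "+".join(t.sample for t in tracks if t.sample) or first.sample
    for t in tracks[1:]:
        for chrom in out.grid.chroms:
            out.values[chrom] += t.values[chrom]
    return out
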