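"""Broad-domain calling from smoothed coverage tracks.

H3K27me3 forms megabase-scale facultative-heterochromatin domains rather than
narrow peaks, so calling works on the genome-wide distribution of binned
signal instead of local peak models:

1. a *domain cutoff* is the smallest bin value strictly greater than the
   values of F% of all genome-wide bins (nearest-rank percentile, zeros
   included; F = 95 by default, 75 for unusually broad/noisy datasets);
2. maximal runs of bins at or above the cutoff are linked, jumping gaps of up
   to 750 bp provided every gap bin holds at least 0.75 × cutoff (tolerates
   short mappability dropouts inside real domains);
3. putative domains are kept only when their mean signal exceeds the matched
   IgG control at least 4-fold (log2 enrichment > 2).

A separate utility coalesces externally annotated chromatin-state segments
(e.g., SEGWAY "FacultativeHet") whose ends lie within a small gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import BinGrid, CoverageTrack

__all__ = [
    "DomainCallParams",
    "Domain",
    "domain_cutoff",
    "link_domains",
    "igg_filter",
    "call_domains",
    "coalesce_segments",
    "domains_to_frame",
    "frame_to_domains",
]


@dataclass(frozen=True)
class DomainCallParams:
    """Tunable parameters of the percentile/gap-jump domain caller."""

    F: float = 95.0                 # percentile defining the domain cutoff
    max_jump: int = 750             # bp; longest bridgeable sub-threshold gap
    jump_frac: float = 0.75         # gap bins must hold >= jump_frac * cutoff
    min_log2_igg: float = 2.0       # keep domains >4-fold over IgG
    igg_pseudocount: float = 0.01   # symmetric epsilon in the IgG log-ratio

    def __post_init__(self) -> None:
        if not 0 < self.F < 100:
            raise ValueError("F must lie strictly between 0 and 100")
        if self.max_jump < 0:
            raise ValueError("max_jump must be non-negative")
        if not 0 < self.jump_frac <= 1:
            raise ValueError("jump_frac must lie in (0, 1]")
        if self.igg_pseudocount <= 0:
            raise ValueError("igg_pseudocount must be positive")


@dataclass
class Domain:
    """A called enriched interval (bp, 0-based half-open, bin-aligned)."""

    chrom: str
    start: int
    end: int
    mean_signal: float = float("nan")
    log2_igg: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty domain [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def domains_to_frame(domains: Sequence[Domain]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.chrom, d.start, d.end, d.mean_signal, d.log2_igg) for d in domains],
        columns=["chrom", "start", "end", "mean_signal", "log2_igg"],
    )


def frame_to_domains(df: pd.DataFrame) -> list[Domain]:
    return [
        Domain(str(r.chrom), int(r.start), int(r.end),
               float(getattr(r, "mean_signal", float("nan"))),
               float(getattr(r, "log2_igg", float("nan"))))
        for r in df.itertuples(index=False)
    ]


def domain_cutoff(track: CoverageTrack, F: float = 95.0) -> float:
    """Smallest bin value strictly greater than the values of F% of all bins.

    Nearest-rank semantics on the genome-wide bin-value distribution, zeros
    included; each bin counts once. Raises on degenerate distributions where
    no observed value exceeds F% of bins (e.g., a constant track).
    """
    if not 0 < F < 100:
        raise ValueError("F must lie strictly between 0 and 100")
    values = track.all_values()
    n = values.size
    if n == 0:
        raise ValueError("empty track")
    uniq, counts = np.unique(values, return_counts=True)
    # bins strictly below each unique value
    less = np.concatenate(([0], np.cumsum(counts)[:-1]))
    need = F * n / 100.0
    ok = np.nonzero(less >= need - 1e-9)[0]
    if ok.size == 0:
        raise ValueError(
            "degenerate bin-value distribution: no bin value exceeds "
            f"{F}% of windows (is the track constant?)"
        )
    return float(uniq[ok[0]])


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) bin-index runs of True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def link_domains(
    track: CoverageTrack,
    cutoff: float,
    params: DomainCallParams = DomainCallParams(),
) -> list[Domain]:
    """Link above-cutoff bin runs into domains, bridging qualifying gaps.

    Two runs merge iff the gap between them is at most ``params.max_jump`` bp
    and *every* gap bin holds at least ``params.jump_frac * cutoff``. Merging
    is applied transitively; domains never span chromosomes. ``mean_signal``
    averages over all included bins, bridged gap bins included.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    w = track.grid.bin_width
    max_gap_bins = params.max_jump // w
    domains: list[Domain] = []
    for chrom in track.grid.chroms:
        v = track.values[chrom]
        runs = _runs_above(v >= cutoff)
        if not runs:
            continue
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            gap = v[pe:s]
            if gap.size <= max_gap_bins and np.all(gap >= params.jump_frac * cutoff):
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        size = int(track.grid.chrom_sizes[chrom])
        for s, e in merged:
            domains.append(
                Domain(
                    chrom=chrom,
                    start=s * w,
                    end=min(e * w, size),
                    mean_signal=float(v[s:e].mean()),
                )
            )
    return domains


def _mean_over_bins(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    w = track.grid.bin_width
    b0, b1 = start // w, -(-end // w)
    return float(track.values[chrom][b0:b1].mean())


def igg_filter(
    domains: Sequence[Domain],
    track: CoverageTrack,
    igg_track: CoverageTrack,
    params: DomainCallParams = DomainCallParams(),
) -> list[Domain]:
    """Keep domains with log2((mean+ε)/(mean_IgG+ε)) > ``min_log2_igg``.

    The pseudocount ε is applied symmetrically so zero-IgG regions stay
    finite and the ordering of ratios is preserved.
    """
    if track.grid != igg_track.grid:
        raise ValueError("signal and IgG tracks must share a grid")
    eps = params.igg_pseudocount
    kept = []
    for d in domains:
        m = _mean_over_bins(track, d.chrom, d.start, d.end)
        mi = _mean_over_bins(igg_track, d.chrom, d.start, d.end)
        l2 = float(np.log2((m + eps) / (mi + eps)))
        if l2 > params.min_log2_igg:
            kept.append(Domain(d.chrom, d.start, d.end, mean_signal=d.mean_signal, log2_igg=l2))
    return kept


def call_domains(
    track: CoverageTrack,
    igg_track: CoverageTrack | None = None,
    params: DomainCallParams = DomainCallParams(),
) -> tuple[list[Domain], float]:
    """Full caller: cutoff → linking → optional IgG filter.

    Returns (domains, cutoff). The track should already be smoothed; the
    caller does not smooth.
    """
    cutoff = domain_cutoff(track, params.F)
    domains = link_domains(track, cutoff, params)
    if igg_track is not None:
        domains = igg_filter(domains, track, igg_track, params)
    return domains, cutoff


def coalesce_segments(
    segments: pd.DataFrame,
    state_label: str,
    max_gap: int = 500,
) -> pd.DataFrame:
    """Merge same-state annotation segments whose ends are within ``max_gap`` bp.

    ``segments`` must carry chrom/start/end plus a ``name`` column with the
    state label (as read from a SEGWAY BED). Merging is transitive within a
    chromosome; returns merged intervals with a ``size`` column, sorted by
    (chrom, start).
    """
    if "name" not in segments.columns:
        raise ValueError("segments need a 'name' column carrying the state label")
    sel = segments.loc[segments["name"] == state_label, ["chrom", "start", "end"]]
    sel = sel.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, sub in sel.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif s - cur_e <= max_gap:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["size"] = out["end"] - out["start"]
    return out
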