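"""Multi-condition domain comparison on disjoint *unique segments*.

Domain sets called in different conditions (time points, treatments) rarely
share boundaries. To compare them, the union of all domains is decomposed at
every boundary coordinate into atomic, pairwise-disjoint *unique segments*
(the `disjoin` of interval algebra); each segment is then wholly inside or
wholly outside every input domain, so per-condition enrichment, clustering
and boundary-change classification are all well defined at segment level.

Boundary changes of a treated domain set against a reference set fall into
four categories:

* ``same``      — segment covered by both a treated and a reference domain;
* ``shrinking`` — reference-only segment (the mark retracted, fully or in part);
* ``spreading`` — treated-only segment belonging to a treated domain that
  still touches a reference domain (the mark extended past old boundaries);
* ``new``       — segment of a treated domain with no reference overlap at all.

Trajectory clustering uses k-means on per-segment log2 enrichment profiles
across conditions; clusters are relabeled 1…k by ascending mean change
(last condition minus first), so cluster 1 always shows the strongest loss
and cluster k the strongest gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .domains import Domain

__all__ = [
    "UniqueSegment",
    "CHANGE_CATEGORIES",
    "reduce",
    "disjoin",
    "segment_enrichment",
    "cluster_segments",
    "classify_change",
    "category_bp_summary",
    "feature_fraction",
    "overlap_bp_with_reference",
    "signal_matrix_around_centers",
    "center_ratio_matrix",
    "segments_to_frame",
]

CHANGE_CATEGORIES = ("same", "shrinking", "spreading", "new")


@dataclass
class UniqueSegment:
    """One atomic interval from a multi-condition disjoin."""

    chrom: str
    start: int
    end: int
    #: condition name -> whether the segment lies inside that condition's domains
    present: dict[str, bool] = field(default_factory=dict)
    #: per-condition mean normalized signal (order = condition order used)
    enrichment: np.ndarray | None = None
    #: per-condition log2(mean + pseudocount)
    log2_row: np.ndarray | None = None
    cluster: int | None = None
    category: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def segments_to_frame(
    segments: Sequence[UniqueSegment], conditions: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabular view of segments (log2 columns expanded per condition)."""
    rows = []
    for s in segments:
        row: dict = {"chrom": s.chrom, "start": s.start, "end": s.end,
                     "cluster": s.cluster, "category": s.category}
        if s.log2_row is not None and conditions is not None:
            for c, v in zip(conditions, s.log2_row):
                row[f"log2_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _by_chrom(domains: Sequence[Domain]) -> dict[str, np.ndarray]:
    """chrom -> (n, 2) sorted interval array."""
    out: dict[str, list[tuple[int, int]]] = {}
    for d in domains:
        out.setdefault(d.chrom, []).append((d.start, d.end))
    return {c: np.array(sorted(iv), dtype=np.int64).reshape(-1, 2) for c, iv in out.items()}


def _merge_sorted(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping or bookended sorted intervals."""
    if len(iv) == 0:
        return iv
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def reduce(domains: Sequence[Domain]) -> list[Domain]:
    """Minimal covering set: merge overlapping or bookended domains."""
    out: list[Domain] = []
    for chrom in sorted({d.chrom for d in domains}):
        iv = _merge_sorted(_by_chrom(domains)[chrom])
        out.extend(Domain(chrom, int(s), int(e)) for s, e in iv)
    return out


def _covered(iv: np.ndarray, point: int) -> bool:
    """Whether a coordinate lies inside one of the sorted disjoint intervals."""
    i = np.searchsorted(iv[:, 0], point, side="right") - 1
    return i >= 0 and point < iv[i, 1]


def disjoin(domain_sets: Mapping[str, Sequence[Domain]]) -> list[UniqueSegment]:
    """Atomic segments induced by all boundaries of all conditions' domains.

    Each condition's domains are reduced first. Output segments are pairwise
    disjoint, their union equals the union of all inputs, and every segment is
    wholly inside or wholly outside each input domain. Segments covered by no
    condition are not emitted.
    """
    conditions = list(domain_sets)
    reduced = {c: _by_chrom(reduce(list(domain_sets[c]))) for c in conditions}
    chroms = sorted({ch for per in reduced.values() for ch in per})
    segments: list[UniqueSegment] = []
    empty = np.empty((0, 2), dtype=np.int64)
    for chrom in chroms:
        per = {c: reduced[c].get(chrom, empty) for c in conditions}
        bounds = np.unique(np.concatenate([iv.ravel() for iv in per.values()]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            present = {c: _covered(per[c], int(a)) if len(per[c]) else False for c in conditions}
            if any(present.values()):
                segments.append(UniqueSegment(chrom, int(a), int(b), present=present))
    return segments


# ---------------------------------------------------------------------------
# Enrichment and clustering
# ---------------------------------------------------------------------------

def segment_enrichment(
    segments: Sequence[UniqueSegment],
    tracks: Mapping[str, CoverageTrack],
    pseudocount: float = 0.01,
) -> list[UniqueSegment]:
    """Attach per-condition mean bin signal and log2(mean+ε) to each segment.

    Segments must be aligned to the shared bin grid (domain callers emit
    bin-aligned intervals).
    """
    conditions = list(tracks)
    grids = {id(t.grid) for t in tracks.values()}
    first = tracks[conditions[0]].grid
    for t in tracks.values():
        if t.grid.chroms != first.chroms or t.grid.bin_width != first.bin_width:
            raise ValueError("tracks must share a grid")
    w = first.bin_width
    out = []
    for s in segments:
        size = int(first.chrom_sizes[s.chrom])
        if s.start % w != 0 or (s.end % w != 0 and s.end != size):
            raise ValueError(
                f"segment {s.chrom}:{s.start}-{s.end} is not aligned to the {w}-bp grid"
            )
        b0, b1 = s.start // w, -(-s.end // w)
        means = np.array([tracks[c].values[s.chrom][b0:b1].mean() for c in conditions])
        out.append(replace(s, enrichment=means, log2_row=np.log2(means + pseudocount)))
    return out


def cluster_segments(
    segments: Sequence[UniqueSegment],
    k: int,
    seed: int,
    n_init: int = 50,
    standardize: bool = True,
    use_log2: bool = True,
) -> list[UniqueSegment]:
    """k-means on per-segment trajectories; labels 1…k ordered by mean change.

    Feature rows are the per-condition log2(mean+ε) values (raw means with
    ``use_log2=False``), optionally z-scored per row so clustering tracks
    trajectory shape and magnitude jointly. Rows are fed to k-means in
    lexicographic order and labels assigned by nearest final center, making
    the result invariant to input segment order for a fixed seed. Clusters
    are relabeled by ascending mean (last − first) log2 change: cluster 1 =
    strongest loss, cluster k = strongest gain.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be at least 2")
    if any(s.log2_row is None for s in segments):
        raise ValueError("segments lack enrichment; run segment_enrichment first")
    X = np.vstack([s.log2_row if use_log2 else s.enrichment for s in segments])
    feats = X
    if standardize:
        mu = feats.mean(axis=1, keepdims=True)
        sd = feats.std(axis=1, keepdims=True)
        feats = np.where(sd > 0, (feats - mu) / np.where(sd == 0, 1, sd), 0.0)
    n_distinct = np.unique(feats, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct feature rows for k={k} clusters")
    order = np.lexsort(feats.T[::-1])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(feats[order])
    centers = km.cluster_centers_
    d2 = ((feats[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    raw_labels = d2.argmin(axis=1)
    # relabel by ascending mean trajectory change (last condition - first)
    change = X[:, -1] - X[:, 0]
    means = np.array([
        change[raw_labels == j].mean() if np.any(raw_labels == j) else np.inf
        for j in range(k)
    ])
    rank = np.empty(k, dtype=int)
    rank[np.argsort(means, kind="stable")] = np.arange(1, k + 1)
    return [replace(s, cluster=int(rank[lbl])) for s, lbl in zip(segments, raw_labels)]


# ---------------------------------------------------------------------------
# Boundary-change classification
# ---------------------------------------------------------------------------

def classify_change(
    treated_domains: Sequence[Domain],
    reference_domains: Sequence[Domain],
    segments: Sequence[UniqueSegment] | None = None,
    on_outside: str = "error",
) -> list[UniqueSegment]:
    """Label segments of the treated/reference union with a change category.

    When ``segments`` is given, those segments are labeled (they must each lie
    wholly inside or outside both domain sets — e.g., the output of a disjoin
    that included both conditions); otherwise the disjoin of the two sets is
    computed and labeled. Reference-only segments are ``shrinking`` even when
    the whole reference domain disappeared (full retraction).
    """
    treated_iv = _by_chrom(reduce(list(treated_domains)))
    ref_iv = _by_chrom(reduce(list(reference_domains)))
    empty = np.empty((0, 2), dtype=np.int64)
    if segments is None:
        segs = disjoin({"treated": list(treated_domains), "reference": list(reference_domains)})
    else:
        segs = list(segments)
    out = []
    for s in segs:
        t = _covered(treated_iv.get(s.chrom, empty), s.start) if s.chrom in treated_iv else False
        r = _covered(ref_iv.get(s.chrom, empty), s.start) if s.chrom in ref_iv else False
        if t and r:
            cat = "same"
        elif r:
            cat = "shrinking"
        elif t:
            iv = treated_iv[s.chrom]
            i = np.searchsorted(iv[:, 0], s.start, side="right") - 1
            parent = iv[i]
            riv = ref_iv.get(s.chrom, empty)
            overlaps = _intersect_bp(riv, int(parent[0]), int(parent[1])) > 0
            cat = "spreading" if overlaps else "new"
        else:
            # can only happen for externally supplied segments present solely
            # in conditions other than the compared pair
            if on_outside == "skip":
                continue
            raise ValueError(
                f"segment {s.chrom}:{s.start}-{s.end} lies outside both domain sets"
            )
        out.append(replace(s, category=cat))
    return out


def _intersect_bp(iv: np.ndarray, start: int, end: int) -> int:
    """Total bp of overlap between [start, end) and sorted disjoint intervals."""
    if len(iv) == 0:
        return 0
    lo = np.minimum(np.maximum(iv[:, 0], start), end)
    hi = np.minimum(np.maximum(iv[:, 1], start), end)
    return int((hi - lo).sum())


# ---------------------------------------------------------------------------
# Per-cluster summaries
# ---------------------------------------------------------------------------

def category_bp_summary(segments: Sequence[UniqueSegment]) -> pd.DataFrame:
    """bp and % bp per (cluster, category); percentages sum to 100 per cluster.

    Every segment must carry both a cluster and a category. Clusters with no
    segments report zero bp, zero percentages and ``empty=True``.
    """
    for s in segments:
        if s.category is None:
            raise ValueError(f"unclassified segment {s.chrom}:{s.start}-{s.end}")
        if s.cluster is None:
            raise ValueError(f"unclustered segment {s.chrom}:{s.start}-{s.end}")
    clusters = sorted({s.cluster for s in segments})
    idx = list(range(1, (max(clusters) if clusters else 0) + 1))
    bp = pd.DataFrame(0, index=idx, columns=list(CHANGE_CATEGORIES), dtype=np.int64)
    for s in segments:
        bp.loc[s.cluster, s.category] += s.length
    total = bp.sum(axis=1)
    pct = bp.div(total.where(total > 0, 1), axis=0) * 100.0
    out = bp.copy()
    out.columns = [f"bp_{c}" for c in CHANGE_CATEGORIES]
    for c in CHANGE_CATEGORIES:
        out[f"pct_{c}"] = pct[c]
    out["total_bp"] = total
    out["empty"] = total == 0
    out.index.name = "cluster"
    return out


def _cluster_groups(segments: Sequence[UniqueSegment]) -> dict[int, list[UniqueSegment]]:
    groups: dict[int, list[UniqueSegment]] = {}
    for s in segments:
        if s.cluster is None:
            raise ValueError("segments must be clustered first")
        groups.setdefault(s.cluster, []).append(s)
    return groups


def feature_fraction(
    segments: Sequence[UniqueSegment], features: pd.DataFrame
) -> pd.Series:
    """% of segments per cluster overlapping ≥1 bp of a feature interval.

    ``features`` is a chrom/start/end DataFrame (CpG islands, bivalent
    promoters, ...).
    """
    feat_iv = {
        chrom: _merge_sorted(
            sub.sort_values(["start", "end"])[["start", "end"]].to_numpy(np.int64)
        )
        for chrom, sub in features.groupby("chrom", sort=False)
    }
    out = {}
    for cl, segs in sorted(_cluster_groups(segments).items()):
        hits = sum(
            1
            for s in segs
            if s.chrom in feat_iv and _intersect_bp(feat_iv[s.chrom], s.start, s.end) > 0
        )
        out[cl] = 100.0 * hits / len(segs)
    return pd.Series(out, name="pct_segments_with_feature").rename_axis("cluster")


def overlap_bp_with_reference(
    segments: Sequence[UniqueSegment], reference_domains: Sequence[Domain]
) -> pd.Series:
    """% of segment bp per cluster that overlaps the reference domain set."""
    ref_iv = _by_chrom(reduce(list(reference_domains)))
    out = {}
    for cl, segs in sorted(_cluster_groups(segments).items()):
        total = sum(s.length for s in segs)
        ov = sum(
            _intersect_bp(ref_iv[s.chrom], s.start, s.end) if s.chrom in ref_iv else 0
            for s in segs
        )
        out[cl] = 100.0 * ov / total if total else 0.0
    return pd.Series(out, name="pct_bp_in_reference").rename_axis("cluster")


# ---------------------------------------------------------------------------
# Center-anchored signal matrices
# ---------------------------------------------------------------------------

def signal_matrix_around_centers(
    domains: Sequence[Domain], track: CoverageTrack, flank: int
) -> np.ndarray:
    """Per-domain rows of bin values centered on the domain midpoint.

    Columns run from −flank to +flank in bin steps (2·flank/bin_width + 1
    columns). Positions beyond the chromosome are NaN.
    """
    w = track.grid.bin_width
    if flank % w != 0:
        raise ValueError("flank must be a multiple of the bin width")
    nf = flank // w
    mat = np.full((len(domains), 2 * nf + 1), np.nan)
    for i, d in enumerate(domains):
        v = track.values[d.chrom]
        cb = ((d.start + d.end) // 2) // w
        lo, hi = cb - nf, cb + nf + 1
        src_lo, src_hi = max(lo, 0), min(hi, len(v))
        mat[i, src_lo - lo : src_hi - lo] = v[src_lo:src_hi]
    return mat


def center_ratio_matrix(
    domains: Sequence[Domain],
    num_track: CoverageTrack,
    den_track: CoverageTrack,
    flank: int,
    pseudocount: float = 0.01,
) -> np.ndarray:
    """Element-wise log2 ratio of two center-anchored matrices.

    Values at matrix positions falling outside the anchoring domain's own
    boundaries are set to 0, so the heatmap shows within-domain change only.
    """
    num = signal_matrix_around_centers(domains, num_track, flank)
    den = signal_matrix_around_centers(domains, den_track, flank)
    ratio = np.log2((num + pseudocount) / (den + pseudocount))
    w = num_track.grid.bin_width
    nf = flank // w
    offsets = np.arange(-nf, nf + 1)
    for i, d in enumerate(domains):
        cb = ((d.start + d.end) // 2) // w
        pos = (cb + offsets) * w  # bin start coordinate of each column
        outside = (pos + w <= d.start) | (pos >= d.end)
        ratio[i, outside] = 0.0
    ratio[np.isnan(ratio)] = 0.0
    return ratio
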