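"""Overlap enrichment and distribution-comparison statistics.

Cross-experiment comparisons ask whether segments of one clustering overlap
segments of another more (or less) often than chance: that is a hypergeometric
draw of cluster-B members from the segment universe, scored against cluster-A
membership, with Benjamini–Hochberg correction over all cluster pairs (both
directions). Distribution shifts (gene expression changes per cluster,
cross-study log2 ratios per group) are compared with two-sided Wilcoxon
rank-sum tests — exact mid-rank enumeration for small samples, the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .segments import UniqueSegment

__all__ = [
    "OverlapTest",
    "hypergeom_overlap",
    "intersect_clusterings",
    "bh_adjust",
    "rank_sum",
    "gene_cluster_expression",
    "group_log2_summary",
]


@dataclass
class OverlapTest:
    cluster_a: Hashable
    cluster_b: Hashable
    k: int       # overlapping units
    K: int       # size of cluster A
    n: int       # size of cluster B
    N: int       # universe size
    p: float     # smaller one-tailed hypergeometric p
    p_adj: float
    direction: str  # "enriched" or "depleted"


def hypergeom_overlap(
    clusters_a: Mapping[Hashable, set],
    clusters_b: Mapping[Hashable, set],
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric overlap tests for every (A-cluster, B-cluster) pair.

    For each pair, the enrichment tail P(X ≥ k) and depletion tail P(X ≤ k)
    are computed for the observed overlap k; the smaller tail is reported with
    its direction, and BH adjustment runs over all pairs × both directions.
    """
    if not universe:
        raise ValueError("empty segment universe")
    N = len(universe)
    rows, pvals = [], []
    for ca, sa in clusters_a.items():
        if not sa <= universe:
            raise ValueError(f"cluster {ca!r} of A contains units outside the universe")
        for cb, sb in clusters_b.items():
            if not sb <= universe:
                raise ValueError(f"cluster {cb!r} of B contains units outside the universe")
            K, n = len(sa), len(sb)
            k = len(sa & sb)
            p_enr = float(hypergeom.sf(k - 1, N, K, n))
            p_dep = float(hypergeom.cdf(k, N, K, n))
            rows.append((ca, cb, k, K, n, N, p_enr, p_dep))
            pvals.extend([p_enr, p_dep])
    adj = bh_adjust(pvals)
    out = []
    for i, (ca, cb, k, K, n, N_, p_enr, p_dep) in enumerate(rows):
        if p_enr <= p_dep:
            p, p_adj, direction = p_enr, adj[2 * i], "enriched"
        else:
            p, p_adj, direction = p_dep, adj[2 * i + 1], "depleted"
        out.append(OverlapTest(ca, cb, k, K, n, N_, p, p_adj, direction))
    return pd.DataFrame([vars(t) for t in out])


def intersect_clusterings(
    segments_a: Sequence[UniqueSegment], segments_b: Sequence[UniqueSegment]
) -> tuple[dict, dict, set]:
    """Atomic correspondence units between two independent segmentations.

    The two segment sets generally have different boundaries; intersecting
    them yields atomic pieces, each inheriting the cluster label of its parent
    in A and in B. Pieces covered by both segmentations form the universe for
    :func:`hypergeom_overlap`; each piece is one sampling unit.
    """
    def index(segs):
        per: dict[str, list[tuple[int, int, int]]] = {}
        for i, s in enumerate(segs):
            per.setdefault(s.chrom, []).append((s.start, s.end, i))
        return {c: sorted(v) for c, v in per.items()}

    ia, ib = index(segments_a), index(segments_b)
    clusters_a: dict = {}
    clusters_b: dict = {}
    universe: set = set()
    for chrom in set(ia) & set(ib):
        bounds = sorted(
            {x for s, e, _ in ia[chrom] for x in (s, e)}
            | {x for s, e, _ in ib[chrom] for x in (s, e)}
        )
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            pa = next((i for s, e, i in ia[chrom] if s <= lo and hi <= e), None)
            pb = next((i for s, e, i in ib[chrom] if s <= lo and hi <= e), None)
            if pa is None or pb is None:
                continue
            unit = (chrom, lo, hi)
            universe.add(unit)
            clusters_a.setdefault(segments_a[pa].cluster, set()).add(unit)
            clusters_b.setdefault(segments_b[pb].cluster, set()).add(unit)
    return clusters_a, clusters_b, universe


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided mid-rank Mann–Whitney p by enumeration of assignments."""
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r_obs = ranks[:n1].sum()
    u_obs = r_obs - n1 * (n1 + 1) / 2
    sums = np.array([sum(c) for c in combinations(ranks, n1)])
    us = sums - n1 * (n1 + 1) / 2
    tol = 1e-9
    p_le = np.mean(us <= u_obs + tol)
    p_ge = np.mean(us >= u_obs - tol)
    p = min(1.0, 2 * min(p_le, p_ge))
    return float(u_obs), float(p)


def rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann–Whitney rank-sum test: (U statistic, p-value).

    Exact enumeration over all rank assignments (mid-ranks, so ties are
    handled) when the combined sample size is ≤ 20; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size <= 20:
        return _exact_rank_sum_p(a, b)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def gene_cluster_expression(
    gene_table: pd.DataFrame,
    segments: Sequence[UniqueSegment],
    lfc_cutoff: float = 1.0,
    fdr_cutoff: float = 0.05,
) -> dict:
    """Per-cluster expression fold-change distributions with pairwise tests.

    ``gene_table`` carries precomputed differential-expression results
    (columns: chrom, start, end, gene_id, log2fc, padj). Significant genes
    (|log2fc| > ``lfc_cutoff`` and padj < ``fdr_cutoff``) are assigned to every
    cluster whose segments they overlap by ≥ 1 bp (multi-membership allowed);
    clusters are compared pairwise by rank-sum with BH adjustment.

    Returns a dict with ``assignments`` (gene_id, cluster, log2fc rows),
    ``tests`` (pairwise comparisons), ``n_unassigned`` and ``n_multi``.
    """
    required = {"chrom", "start", "end", "gene_id", "log2fc", "padj"}
    missing = required - set(gene_table.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    sig = gene_table.loc[
        (gene_table["log2fc"].abs() > lfc_cutoff) & (gene_table["padj"] < fdr_cutoff)
    ]
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for s in segments:
        if s.cluster is None:
            raise ValueError("segments must carry cluster labels")
        per_chrom.setdefault(s.chrom, []).append((s.start, s.end, s.cluster))
    rows, n_unassigned, n_multi = [], 0, 0
    for g in sig.itertuples(index=False):
        hits = {
            cl
            for (s, e, cl) in per_chrom.get(str(g.chrom), [])
            if min(e, g.end) - max(s, g.start) > 0
        }
        if not hits:
            n_unassigned += 1
            continue
        if len(hits) > 1:
            n_multi += 1
        for cl in sorted(hits):
            rows.append((g.gene_id, cl, float(g.log2fc)))
    assignments = pd.DataFrame(rows, columns=["gene_id", "cluster", "log2fc"])
    tests = _pairwise_rank_sum(
        {cl: sub["log2fc"].to_numpy() for cl, sub in assignments.groupby("cluster")}
    )
    return {
        "assignments": assignments,
        "tests": tests,
        "n_unassigned": n_unassigned,
        "n_multi": n_multi,
    }


def _pairwise_rank_sum(groups: Mapping[Hashable, np.ndarray]) -> pd.DataFrame:
    keys = [k for k in groups if len(groups[k]) > 0]
    pairs = [(x, y) for i, x in enumerate(keys) for y in keys[i + 1 :]]
    rows = []
    for x, y in pairs:
        if len(groups[x]) < 2 or len(groups[y]) < 2:
            continue  # a single observation supports no comparison
        u, p = rank_sum(groups[x], groups[y])
        rows.append((x, y, u, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p"])
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def group_log2_summary(
    group_labels: Sequence[str], values: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median/quartile summaries per group plus pairwise rank-sum tests.

    ``group_labels`` and ``values`` are parallel per-segment arrays (e.g., the
    CL1–CL3 mixture groups against an external study's log2 ratios). Segments
    with missing values are dropped; the summary records how many.
    """
    labels = np.asarray(group_labels, dtype=object)
    vals = np.asarray(values, dtype=float)
    if labels.shape != vals.shape:
        raise ValueError("group labels and values must align")
    keep = ~np.isnan(vals)
    n_dropped = int((~keep).sum())
    labels, vals = labels[keep], vals[keep]
    rows = []
    groups: dict[Hashable, np.ndarray] = {}
    for g in pd.unique(labels):
        v = vals[labels == g]
        groups[g] = v
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append((g, len(v), med, q1, q3, n_dropped))
    summary = pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3", "n_dropped"])
    tests = _pairwise_rank_sum(groups)
    return summary, tests
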