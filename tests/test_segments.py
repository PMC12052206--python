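"""Disjoin/reduce interval algebra, clustering, change classification, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from k27domains import (
    category_bp_summary,
    center_ratio_matrix,
    classify_change,
    cluster_segments,
    disjoin,
    feature_fraction,
    overlap_bp_with_reference,
    reduce,
    segment_enrichment,
    signal_matrix_around_centers,
)
from k27domains.domains import Domain
from k27domains.segments import UniqueSegment

from conftest import make_track


def doms(*ivs, chrom="chr1"):
    return [Domain(chrom, s, e) for s, e in ivs]


def bp_label_oracle(domain_sets, length):
    """Per-bp membership vectors; the ground truth disjoin is their run-length
    encoding over the union."""
    conds = list(domain_sets)
    cover = {c: np.zeros(length, dtype=bool) for c in conds}
    for c, ds in domain_sets.items():
        for d in ds:
            cover[c][d.start:d.end] = True
    stack = np.vstack([cover[c] for c in conds])
    segs = []
    start = None
    for pos in range(length + 1):
        cur = tuple(stack[:, pos]) if pos < length and stack[:, pos].any() else None
        prev = tuple(stack[:, pos - 1]) if pos > 0 and stack[:, pos - 1].any() else None
        if cur != prev:
            if prev is not None:
                segs.append((start, pos, prev))
            start = pos
    return conds, segs


class TestReduce:
    def test_bookended_intervals_merge(self):
        out = reduce(doms((0, 100), (100, 200)))
        assert [(d.start, d.end) for d in out] == [(0, 200)]

    def test_disjoint_input_identity(self):
        out = reduce(doms((0, 100), (300, 400)))
        assert [(d.start, d.end) for d in out] == [(0, 100), (300, 400)]

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)), min_size=1, max_size=30))
    def test_matches_union_oracle(self, pairs):
        ds = doms(*[(s, s + l) for s, l in pairs])
        out = reduce(ds)
        mask = np.zeros(600, dtype=bool)
        for s, l in pairs:
            mask[s:s + l] = True
        got = np.zeros(600, dtype=bool)
        for d in out:
            assert not got[d.start:d.end].any()  # pairwise disjoint
            got[d.start:d.end] = True
        assert (got == mask).all()


class TestDisjoin:
    def test_two_overlapping_conditions(self):
        segs = disjoin({"A": doms((0, 300)), "B": doms((100, 400))})
        assert [(s.start, s.end) for s in segs] == [(0, 100), (100, 300), (300, 400)]
        assert [s.present for s in segs] == [
            {"A": True, "B": False},
            {"A": True, "B": True},
            {"A": False, "B": True},
        ]

    def test_identical_sets_yield_input_intervals(self):
        a = doms((0, 500), (1000, 1500))
        segs = disjoin({"A": a, "B": doms((0, 500), (1000, 1500))})
        assert [(s.start, s.end) for s in segs] == [(0, 500), (1000, 1500)]

    def test_matches_per_bp_oracle_on_random_sets(self, rng):
        length = 100_000
        for _ in range(60):
            sets = {}
            for c in ("A", "B", "C"):
                starts = np.sort(rng.integers(0, length - 4000, rng.integers(1, 12)))
                sets[c] = reduce(doms(*[(int(s), int(s) + int(rng.integers(100, 4000)))
                                        for s in starts]))
            segs = disjoin(sets)
            conds, expected = bp_label_oracle(sets, length)
            got = [(s.start, s.end, tuple(s.present[c] for c in conds)) for s in segs]
            assert got == expected

    def test_partition_property(self, rng):
        sets = {
            "A": doms((0, 1000), (5000, 9000)),
            "B": doms((500, 6000)),
            "C": doms((8000, 12000)),
        }
        segs = disjoin(sets)
        # pairwise disjoint and union preserved
        covered = np.zeros(12000, dtype=bool)
        for s in segs:
            assert not covered[s.start:s.end].any()
            covered[s.start:s.end] = True
        union = np.zeros(12000, dtype=bool)
        for ds in sets.values():
            for d in ds:
                union[d.start:d.end] = True
        assert (covered == union).all()
        # each segment wholly in or out of every input domain
        for s in segs:
            for c, ds in sets.items():
                for d in ds:
                    ov = min(s.end, d.end) - max(s.start, d.start)
                    assert ov <= 0 or ov == s.end - s.start


class TestSegmentEnrichment:
    def test_constant_track_gives_constant_means(self):
        tracks = {"a": make_track([7.0] * 20), "b": make_track([3.0] * 20)}
        segs = disjoin({"x": doms((0, 500), (800, 1200))})
        out = segment_enrichment(segs, tracks, pseudocount=0.0)
        for s in out:
            np.testing.assert_allclose(s.enrichment, [7.0, 3.0])
            np.testing.assert_allclose(s.log2_row, [np.log2(7), np.log2(3)])

    def test_mean_over_covered_bins(self):
        vals = np.arange(10, dtype=float)
        tracks = {"a": make_track(vals)}
        segs = disjoin({"x": doms((200, 500))})  # bins 2,3,4
        out = segment_enrichment(segs, tracks, pseudocount=0.0)
        assert out[0].enrichment[0] == pytest.approx(3.0)

    def test_off_grid_segment_rejected(self):
        tracks = {"a": make_track([1.0] * 10)}
        seg = UniqueSegment("chr1", 150, 400)
        with pytest.raises(ValueError, match="grid"):
            segment_enrichment([seg], tracks)

    def test_matches_direct_averaging_oracle(self, rng):
        vals = rng.random(50) * 9
        tracks = {"a": make_track(vals)}
        segs = disjoin({"x": doms((400, 900), (2100, 4800))})
        out = segment_enrichment(segs, tracks, pseudocount=0.0)
        for s in out:
            expected = vals[s.start // 100: s.end // 100].mean()
            assert s.enrichment[0] == pytest.approx(expected)


def _segments_with_rows(rows, length=1000):
    segs = []
    for i, row in enumerate(rows):
        s = UniqueSegment("chr1", i * length, (i + 1) * length)
        s.enrichment = np.exp2(np.asarray(row, dtype=float))
        s.log2_row = np.asarray(row, dtype=float)
        segs.append(s)
    return segs


class TestClusterSegments:
    def test_separated_blobs_recovered(self, rng):
        loss = [[2.0 + rng.normal(0, 0.05), 1.0, 0.0 + rng.normal(0, 0.05)] for _ in range(30)]
        gain = [[0.0 + rng.normal(0, 0.05), 1.0, 2.0 + rng.normal(0, 0.05)] for _ in range(30)]
        segs = _segments_with_rows(loss + gain)
        out = cluster_segments(segs, k=2, seed=5)
        labels = [s.cluster for s in out]
        assert labels[:30] == [1] * 30  # strongest loss is cluster 1
        assert labels[30:] == [2] * 30

    def test_identical_rows_rejected(self):
        segs = _segments_with_rows([[1.0, 2.0]] * 10)
        with pytest.raises(ValueError, match="distinct"):
            cluster_segments(segs, k=2, seed=0)

    def test_relabeling_orders_clusters_by_mean_change(self, rng):
        rows = [[rng.normal(), rng.normal(), rng.normal()] for _ in range(60)]
        out = cluster_segments(_segments_with_rows(rows), k=4, seed=1)
        means = {}
        for s in out:
            means.setdefault(s.cluster, []).append(s.log2_row[-1] - s.log2_row[0])
        ordered = [np.mean(means[c]) for c in sorted(means)]
        assert ordered == sorted(ordered)

    def test_input_order_invariance(self, rng):
        rows = [list(rng.normal(size=4)) for _ in range(80)]
        base = cluster_segments(_segments_with_rows(rows), k=3, seed=9)
        base_labels = {(s.start): s.cluster for s in base}
        perm = list(rng.permutation(80))
        segs2 = _segments_with_rows([rows[i] for i in perm])
        # rebuild with original coordinates so identity is traceable
        for s, i in zip(segs2, perm):
            s.start, s.end = i * 1000, (i + 1) * 1000
        out2 = cluster_segments(segs2, k=3, seed=9)
        assert {(s.start): s.cluster for s in out2} == base_labels


class TestClassifyChange:
    def test_identical_domain_is_same(self):
        segs = classify_change(doms((1000, 2000)), doms((1000, 2000)))
        assert [(s.start, s.end, s.category) for s in segs] == [(1000, 2000, "same")]

    def test_extension_splits_into_spreading_plus_same(self):
        segs = classify_change(doms((800, 2000)), doms((1000, 2000)))
        assert [(s.start, s.end, s.category) for s in segs] == [
            (800, 1000, "spreading"),
            (1000, 2000, "same"),
        ]

    def test_no_reference_overlap_is_new(self):
        segs = classify_change(doms((5000, 6000)), doms((1000, 2000)))
        by_cat = {s.category for s in segs if s.start == 5000}
        assert by_cat == {"new"}

    def test_reference_only_is_shrinking_even_when_fully_lost(self):
        segs = classify_change(doms((1000, 1500)), doms((1000, 2000), (8000, 9000)))
        cats = {(s.start, s.end): s.category for s in segs}
        assert cats[(1500, 2000)] == "shrinking"
        assert cats[(8000, 9000)] == "shrinking"

    def test_domain_can_shrink_one_end_and_spread_the_other(self):
        segs = classify_change(doms((500, 1800)), doms((1000, 2000)))
        cats = {(s.start, s.end): s.category for s in segs}
        assert cats == {
            (500, 1000): "spreading",
            (1000, 1800): "same",
            (1800, 2000): "shrinking",
        }

    def test_every_union_bp_gets_exactly_one_category(self, rng):
        for _ in range(30):
            t = reduce(doms(*[(int(s), int(s) + int(rng.integers(100, 3000)))
                              for s in rng.integers(0, 50_000, 8)]))
            r = reduce(doms(*[(int(s), int(s) + int(rng.integers(100, 3000)))
                              for s in rng.integers(0, 50_000, 8)]))
            segs = classify_change(t, r)
            covered = np.zeros(60_000, dtype=np.int8)
            for s in segs:
                assert s.category in ("same", "shrinking", "spreading", "new")
                covered[s.start:s.end] += 1
            union = np.zeros(60_000, dtype=bool)
            for d in list(t) + list(r):
                union[d.start:d.end] = True
            assert (covered[union] == 1).all() and (covered[~union] == 0).all()


class TestCategorySummary:
    def seg(self, start, end, cluster, category):
        s = UniqueSegment("chr1", start, end)
        s.cluster, s.category = cluster, category
        return s

    def test_single_new_segment_is_hundred_percent(self):
        table = category_bp_summary([self.seg(0, 1000, 6, "new")])
        assert table.loc[6, "bp_new"] == 1000
        assert table.loc[6, "pct_new"] == pytest.approx(100.0)

    def test_empty_cluster_reports_zero_with_flag(self):
        table = category_bp_summary([self.seg(0, 1000, 3, "same")])
        assert table.loc[1, "empty"] and table.loc[1, "total_bp"] == 0
        assert not table.loc[3, "empty"]

    def test_percentages_sum_to_hundred(self, rng):
        segs = [
            self.seg(i * 1000, i * 1000 + int(rng.integers(100, 900)),
                     int(rng.integers(1, 4)),
                     ["same", "shrinking", "spreading", "new"][rng.integers(0, 4)])
            for i in range(50)
        ]
        table = category_bp_summary(segs)
        pct = table.loc[~table["empty"], [c for c in table.columns if c.startswith("pct_")]]
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, rtol=1e-9)

    def test_unclassified_segment_rejected(self):
        s = UniqueSegment("chr1", 0, 100)
        s.cluster = 1
        with pytest.raises(ValueError, match="unclassified"):
            category_bp_summary([s])


class TestFeatureOverlap:
    def clustered(self, n, cluster, rng):
        segs = []
        for i in range(n):
            s = UniqueSegment("chr1", i * 2000, i * 2000 + 1000)
            s.cluster = cluster
            segs.append(s)
        return segs

    def test_feature_in_every_segment_gives_hundred(self, rng):
        segs = self.clustered(5, 1, rng)
        feats = pd.DataFrame(
            [("chr1", s.start + 10, s.start + 20) for s in segs],
            columns=["chrom", "start", "end"],
        )
        assert feature_fraction(segs, feats)[1] == pytest.approx(100.0)

    def test_no_features_gives_zero(self, rng):
        segs = self.clustered(5, 2, rng)
        feats = pd.DataFrame(columns=["chrom", "start", "end"])
        assert feature_fraction(segs, feats)[2] == 0.0

    def test_random_matches_pairwise_overlap_count(self, rng):
        segs = self.clustered(40, 1, rng)
        feats = pd.DataFrame(
            [("chr1", int(s), int(s) + 300) for s in rng.integers(0, 80_000, 30)],
            columns=["chrom", "start", "end"],
        )
        got = feature_fraction(segs, feats)[1]
        hits = sum(
            1 for s in segs
            if any(f.start < s.end and f.end > s.start for f in feats.itertuples())
        )
        assert got == pytest.approx(100.0 * hits / len(segs))

    def test_overlap_bp_identical_and_disjoint(self, rng):
        segs = self.clustered(4, 1, rng)
        same_ref = [Domain("chr1", s.start, s.end) for s in segs]
        assert overlap_bp_with_reference(segs, same_ref)[1] == pytest.approx(100.0)
        far_ref = [Domain("chr1", 500_000, 501_000)]
        assert overlap_bp_with_reference(segs, far_ref)[1] == 0.0

    def test_overlap_bp_matches_per_bp_oracle(self, rng):
        segs = self.clustered(30, 1, rng)
        ref = reduce(doms(*[(int(s), int(s) + int(rng.integers(200, 5000)))
                            for s in rng.integers(0, 60_000, 12)]))
        got = overlap_bp_with_reference(segs, ref)[1]
        mask = np.zeros(100_000, dtype=bool)
        for d in ref:
            mask[d.start:d.end] = True
        ov = sum(mask[s.start:s.end].sum() for s in segs)
        total = sum(s.end - s.start for s in segs)
        assert got == pytest.approx(100.0 * ov / total)


class TestCenterMatrices:
    def test_constant_track_gives_constant_rows(self):
        track = make_track([4.0] * 100)
        mat = signal_matrix_around_centers(doms((3000, 5000)), track, flank=1000)
        np.testing.assert_allclose(mat, 4.0)
        assert mat.shape == (1, 21)

    def test_ratio_of_track_to_itself_is_zero_everywhere(self):
        track = make_track(np.linspace(1, 9, 100))
        mat = center_ratio_matrix(doms((3000, 5000)), track, track, flank=2000)
        np.testing.assert_allclose(mat, 0.0)

    def test_zeroing_outside_domain_boundaries(self):
        num = make_track([8.0] * 100)
        den = make_track([2.0] * 100)
        mat = center_ratio_matrix(doms((4000, 5000)), num, den, flank=2000, pseudocount=0.0)
        inside = mat[0, mat[0] != 0]
        assert np.allclose(inside, 2.0)  # log2(8/2) within the domain
        assert len(inside) == 10  # the domain's own ten bins
        # columns fully outside [4000, 5000) must be zeroed
        assert mat[0, 0] == 0.0 and mat[0, -1] == 0.0

    def test_row_indexing_matches_direct_lookup(self, rng):
        vals = rng.random(200) * 7
        track = make_track(vals)
        d = doms((8200, 9400))
        mat = signal_matrix_around_centers(d, track, flank=500)
        center_bin = ((8200 + 9400) // 2) // 100
        np.testing.assert_allclose(mat[0], vals[center_bin - 5: center_bin + 6])

    def test_chromosome_edge_padded_with_nan(self):
        track = make_track([1.0] * 30)
        mat = signal_matrix_around_centers(doms((0, 400)), track, flank=1000)
        assert np.isnan(mat[0, :8]).all()
        assert np.isfinite(mat[0, 10:]).all()
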