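"""Fragment filtering, normalization factors, binning and smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from k27domains import (
    BinGrid,
    bin_coverage,
    combine_replicates,
    dedup_fragments,
    depth_factor,
    extend_single_end,
    filter_fragments,
    smooth_running_average,
    spike_in_factor,
)
from k27domains.coverage import fragments_frame

from conftest import make_track


def frags(*triples):
    return fragments_frame(triples)


class TestFilterFragments:
    def test_length_window_bounds_are_inclusive(self):
        f = frags(*((("chr1", 0, L)) for L in (100, 119, 120, 500, 501)))
        kept = filter_fragments(f, 120, 500)
        assert sorted(kept["end"] - kept["start"]) == [120, 500]

    def test_empty_input_and_identity_window(self):
        assert len(filter_fragments(frags(), 120, 500)) == 0
        f = frags(("chr1", 0, 75), ("chr1", 10, 900))
        assert len(filter_fragments(f, 1, 10**9)) == 2

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            filter_fragments(frags(), 500, 120)


class TestDedupFragments:
    def test_exact_duplicates_collapse_to_first(self):
        f = frags(("chr1", 10, 200), ("chr1", 10, 200), ("chr1", 10, 201))
        assert len(dedup_fragments(f)) == 2

    def test_matches_set_oracle_on_planted_duplicates(self, rng):
        base = [("chr%d" % rng.integers(1, 3), int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 5000, 1000), rng.integers(50, 400, 1000))]
        # plant duplicates by resampling rows
        rows = base + [base[i] for i in rng.integers(0, len(base), 300)]
        out = dedup_fragments(frags(*rows))
        assert len(out) == len(set(rows))

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20)), max_size=30))
    def test_idempotent(self, pairs):
        f = frags(*[("chr1", s, s + l) for s, l in pairs])
        once = dedup_fragments(f)
        twice = dedup_fragments(once)
        pd.testing.assert_frame_equal(once, twice)


class TestExtendSingleEnd:
    sizes = {"chr1": 10_000}

    def test_plus_strand_extends_from_five_prime(self):
        reads = fragments_frame([("chr1", 1000, 1050, "+")], strand=True)
        out = extend_single_end(reads, self.sizes)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (1000, 1250)

    def test_minus_strand_mirrors(self):
        reads = fragments_frame([("chr1", 4950, 5000, "-")], strand=True)
        out = extend_single_end(reads, self.sizes)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (4750, 5000)

    def test_clipped_at_chromosome_end(self):
        reads = fragments_frame([("chr1", 9950, 10_000, "+"), ("chr1", 0, 50, "-")], strand=True)
        out = extend_single_end(reads, self.sizes)
        assert out.loc[0, "end"] == 10_000
        assert out.loc[1, "start"] == 0

    def test_missing_strand_errors(self):
        with pytest.raises(ValueError, match="strand"):
            extend_single_end(frags(("chr1", 0, 50)), self.sizes)


@pytest.mark.parametrize(
    "func,arg,expected",
    [
        (spike_in_factor, 10_000, 1.0),
        (spike_in_factor, 2_500, 4.0),
        (depth_factor, 2_800_000_000, 1.0),
        (depth_factor, 28_000_000, 100.0),
    ],
)
def test_normalization_factors(func, arg, expected):
    assert func(arg) == pytest.approx(expected)


@pytest.mark.parametrize("func", [spike_in_factor, depth_factor])
def test_normalization_factor_rejects_zero(func):
    with pytest.raises(ValueError):
        func(0)


class TestBinCoverage:
    def test_fragment_increments_every_overlapped_bin(self):
        grid = BinGrid({"chr1": 1000})
        track = bin_coverage(frags(("chr1", 150, 270)), grid, factor=2.0)
        assert list(track.values["chr1"]) == [0, 2.0, 2.0, 0, 0, 0, 0, 0, 0, 0]

    def test_no_fragments_gives_zero_track(self):
        track = bin_coverage(frags(), BinGrid({"chr1": 1000}), factor=1.0)
        assert track.all_values().sum() == 0

    def test_unknown_chromosome_named_in_error(self):
        with pytest.raises(ValueError, match="chrX"):
            bin_coverage(frags(("chrX", 0, 100)), BinGrid({"chr1": 1000}), 1.0)

    def test_matches_brute_force_overlap_oracle(self, rng):
        grid = BinGrid({"chr1": 20_000, "chr2": 10_000})
        rows = []
        for _ in range(5_000):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            size = grid.chrom_sizes[chrom]
            start = int(rng.integers(0, size - 600))
            rows.append((chrom, start, start + int(rng.integers(1, 600))))
        factor = 0.37
        track = bin_coverage(frags(*rows), grid, factor)
        for chrom in grid.chroms:
            w = grid.bin_width
            expected = np.zeros(grid.n_bins(chrom))
            for i in range(len(expected)):
                b0, b1 = i * w, (i + 1) * w
                expected[i] = factor * sum(
                    1 for c, s, e in rows if c == chrom and s < b1 and e > b0
                )
            np.testing.assert_allclose(track.values[chrom], expected)

    def test_mass_bookkeeping(self, rng):
        grid = BinGrid({"chr1": 50_000})
        rows = [("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 49_000, 2_000), rng.integers(1, 900, 2_000))]
        factor = 1.7
        track = bin_coverage(frags(*rows), grid, factor)
        w = grid.bin_width
        bins_per_frag = sum((e - 1) // w - s // w + 1 for _, s, e in rows)
        assert track.all_values().sum() == pytest.approx(factor * bins_per_frag, rel=1e-9)

    def test_midpoint_mode_assigns_single_bin(self):
        grid = BinGrid({"chr1": 1000})
        track = bin_coverage(frags(("chr1", 150, 270)), grid, 1.0, midpoint=True)
        assert track.all_values().sum() == 1.0
        assert track.values["chr1"][2] == 1.0  # midpoint 210


class TestSmoothing:
    def test_constant_track_unchanged(self):
        track = make_track([5.0] * 60)
        out = smooth_running_average(track)
        np.testing.assert_allclose(out.values["chr1"], 5.0)
        assert out.smoothed

    def test_interior_impulse_spreads_over_window(self):
        v = 42.0
        track = make_track([0.0] * 25 + [v] + [0.0] * 25)
        out = smooth_running_average(track, half_span=1000)
        got = out.values["chr1"]
        np.testing.assert_allclose(got[15:36], v / 21)
        assert got[14] == 0 and got[36] == 0

    def test_edge_impulse_uses_truncated_window(self):
        v = 33.0
        track = make_track([v] + [0.0] * 40)
        out = smooth_running_average(track, half_span=1000)
        assert out.values["chr1"][0] == pytest.approx(v / 11)

    def test_interior_conservation(self, rng):
        vals = np.zeros(200)
        vals[30:170] = rng.random(140) * 10
        track = make_track(vals)
        out = smooth_running_average(track)
        assert out.all_values().sum() == pytest.approx(vals.sum(), rel=1e-9)

    def test_double_smoothing_refused(self):
        out = smooth_running_average(make_track([1.0] * 30))
        with pytest.raises(ValueError, match="smooth"):
            smooth_running_average(out)

    def test_half_span_must_align_to_bins(self):
        with pytest.raises(ValueError):
            smooth_running_average(make_track([1.0] * 30), half_span=150)


class TestCombineReplicates:
    def test_single_input_identity_and_triple_sum(self, rng):
        vals = rng.random(50)
        t = make_track(vals)
        np.testing.assert_allclose(combine_replicates([t]).values["chr1"], vals)
        triple = combine_replicates([make_track(vals) for _ in range(3)])
        np.testing.assert_allclose(triple.values["chr1"], 3 * vals)

    def test_random_triple_matches_elementwise_sum(self, rng):
        tracks = [make_track(rng.random(80)) for _ in range(3)]
        out = combine_replicates(tracks)
        expected = sum(t.values["chr1"] for t in tracks)
        np.testing.assert_allclose(out.values["chr1"], expected)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            combine_replicates([make_track([1.0] * 10), make_track([1.0] * 11)])

    def test_smoothing_state_mismatch_rejected(self):
        a = make_track([1.0] * 10)
        b = smooth_running_average(make_track([1.0] * 10))
        with pytest.raises(ValueError):
            combine_replicates([a, b])


def test_spike_normalization_scale_invariance(rng):
    """Replicating every fragment (target and spike-in) c-fold leaves the
    spike-normalized track unchanged: the factor halves as the counts double."""
    grid = BinGrid({"chr1": 30_000})
    rows = [("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 29_000, 800), rng.integers(100, 500, 800))]
    n_spike = 2_000
    base = bin_coverage(frags(*rows), grid, spike_in_factor(n_spike))
    for c in (2, 5):
        scaled = bin_coverage(frags(*(rows * c)), grid, spike_in_factor(n_spike * c))
        assert scaled.allclose(base, rtol=1e-9)
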