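import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleodyn import genome_io as gio
from nucleodyn import occupancy as oc


class TestTiling:
    def test_remainder_window_flagged_partial(self):
        grid = oc.tile_genome(gio.GenomeIndex(("chr1",), (12_000,)), 5_000)
        assert list(grid.starts) == [0, 5_000, 10_000]
        assert list(grid.ends) == [5_000, 10_000, 12_000]
        assert list(grid.partial) == [False, False, True]

    def test_exact_fit_single_window(self):
        grid = oc.tile_genome(gio.GenomeIndex(("chr1",), (5_000,)), 5_000)
        assert grid.n == 1 and not grid.partial[0]

    def test_windows_never_span_chromosomes(self, small_index):
        grid = oc.tile_genome(small_index, 7_000)
        for chrom in small_index.names:
            sel = grid.chroms == chrom
            assert grid.ends[sel].max() <= small_index.length(chrom)
            assert grid.starts[sel].min() == 0

    def test_bad_window_size(self, small_index):
        with pytest.raises(ValueError):
            oc.tile_genome(small_index, 0)


class TestCounting:
    def test_half_open_boundary(self):
        grid = oc.tile_genome(gio.GenomeIndex(("chr1",), (10_000,)), 5_000)
        counts = oc.count_in_windows({"chr1": np.array([100, 4_999, 5_000])}, grid)
        assert list(counts) == [2, 1]

    def test_empty_midpoints(self):
        grid = oc.tile_genome(gio.GenomeIndex(("chr1",), (10_000,)), 5_000)
        assert oc.count_in_windows({}, grid).sum() == 0

    def test_matches_per_midpoint_scan(self, rng, small_index):
        grid = oc.tile_genome(small_index, 3_000)
        mids = {
            "chr1": np.sort(rng.integers(0, 100_000, 700)),
            "chr2": np.sort(rng.integers(0, 60_000, 300)),
        }
        fast = oc.count_in_windows(mids, grid)
        slow = np.zeros(grid.n, dtype=int)
        for chrom, arr in mids.items():
            for m in arr:
                for i in range(grid.n):
                    if grid.chroms[i] == chrom and grid.starts[i] <= m < grid.ends[i]:
                        slow[i] += 1
        assert list(fast) == list(slow)
        assert fast.sum() == 1_000

    def test_midpoint_beyond_end_errors(self):
        grid = oc.tile_genome(gio.GenomeIndex(("chr1",), (10_000,)), 5_000)
        with pytest.raises(ValueError):
            oc.count_in_windows({"chr1": np.array([10_000])}, grid)


class TestLogRatio:
    def test_symmetric_counts_give_zero(self):
        q, low = oc.log_ratio(np.array([100.0]), np.array([100.0]), 0.5, 0)
        assert q[0] == 0.0 and not low[0]

    def test_fourfold_ratio(self):
        # equal library totals so depth normalization is a no-op
        q, _ = oc.log_ratio(np.array([8.0, 2.0]), np.array([2.0, 8.0]), 0.0, 0)
        assert q[0] == pytest.approx(2.0)

    def test_zero_counts_with_pseudocount(self):
        q, _ = oc.log_ratio(np.array([0.0, 5.0]), np.array([0.0, 5.0]), 0.5, 0)
        assert q[0] == 0.0

    def test_zero_pseudocount_with_zero_count_errors(self):
        with pytest.raises(ValueError):
            oc.log_ratio(np.array([0.0, 4.0]), np.array([3.0, 4.0]), 0.0, 0)

    def test_low_coverage_masked(self):
        q, low = oc.log_ratio(np.array([5.0, 50.0]), np.array([5.0, 50.0]), 0.5, 20)
        assert list(low) == [True, False]


class TestCentering:
    def test_simple(self):
        np.testing.assert_allclose(oc.center(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_constant(self):
        np.testing.assert_allclose(oc.center(np.array([5.0, 5.0, 5.0])), [0, 0, 0])

    def test_all_masked_errors(self):
        with pytest.raises(ValueError):
            oc.center(np.array([1.0]), np.array([True]))

    def test_library_scaling_leaves_centered_unchanged(self, rng):
        r = rng.poisson(100, 500).astype(float)
        s = rng.poisson(100, 500).astype(float)
        q1, low1 = oc.log_ratio(r, s, 0.5, 20)
        q3, low3 = oc.log_ratio(r, 3 * s, 0.5, 20)
        assert list(low1) == list(low3)
        np.testing.assert_allclose(oc.center(q1, low1), oc.center(q3, low3), atol=1e-12)


class TestNull:
    def test_empirical_cdf_convention(self):
        null = oc.InertNull(values=np.array([-1.0, 0.0, 1.0]))
        assert null.cdf(0.0) == pytest.approx(2 / 3)

    def test_degenerate_null_rejected(self):
        centered = np.zeros(200)
        with pytest.raises(ValueError, match="degenerate"):
            oc.build_null(centered, np.ones(200, dtype=bool), min_inert=100)

    def test_too_few_inert_windows(self):
        centered = np.random.default_rng(0).normal(size=50)
        with pytest.raises(ValueError, match="inert"):
            oc.build_null(centered, np.ones(50, dtype=bool), min_inert=100)

    def test_low_coverage_windows_excluded(self):
        centered = np.arange(300.0)
        low = np.zeros(300, dtype=bool)
        low[:150] = True
        null = oc.build_null(centered, np.ones(300, dtype=bool), low, min_inert=100)
        assert null.n == 150 and null.values.min() == 150.0


class TestEmpiricalPvalue:
    NULL = oc.InertNull(values=np.array([0.1, 0.2, 0.3, 0.4]))

    @pytest.mark.parametrize(
        "x,side,expected",
        [
            (0.35, "depletion_at_t2", (1 + 1) / (1 + 4)),
            (-1.0, "depletion_at_t2", 1.0),
            (0.5, "depletion_at_t2", (1 + 0) / (1 + 4)),
            (0.5, "enrichment_at_t2", 1.0),
            (0.05, "enrichment_at_t2", (1 + 0) / (1 + 4)),
        ],
    )
    def test_rank_count_convention(self, x, side, expected):
        assert oc.empirical_pvalue(np.array([x]), self.NULL, side)[0] == pytest.approx(expected)

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            oc.empirical_pvalue(np.array([0.0]), self.NULL, "both")

    def test_monotone_in_centered_value(self, rng):
        null = oc.InertNull(values=np.sort(rng.normal(size=500)))
        xs = np.sort(rng.normal(size=300))
        p = oc.empirical_pvalue(xs, null, "depletion_at_t2")
        assert np.all(np.diff(p) <= 0)

    def test_never_zero_or_above_one(self, rng):
        null = oc.InertNull(values=np.sort(rng.normal(size=100)))
        p = oc.empirical_pvalue(rng.normal(size=1_000), null, "enrichment_at_t2")
        assert np.all(p > 0) and np.all(p <= 1)


class TestLabelling:
    def test_bh_matches_brute_force_step_up(self, rng):
        p_right = np.array([0.01, 0.02, 0.04, 0.05])
        labels = oc.label_windows(p_right, np.ones(4), alpha=0.05, correction="bh")
        assert list(labels) == ["depleted"] * 4

        p = rng.uniform(size=200)
        labels = oc.label_windows(p, np.ones(200), alpha=0.05, correction="bh")
        # brute-force BH: largest k with p_(k) <= alpha*k/n, reject the k smallest
        order = np.argsort(p)
        ks = np.flatnonzero(p[order] <= 0.05 * np.arange(1, 201) / 200)
        expect = np.zeros(200, dtype=bool)
        if len(ks):
            expect[order[: ks[-1] + 1]] = True
        assert list(labels == "depleted") == list(expect)

    def test_all_unit_pvalues_unchanged(self):
        labels = oc.label_windows(np.ones(10), np.ones(10))
        assert set(labels) == {"unchanged"}

    def test_raw_threshold_mode(self):
        p_right = np.array([0.01, 0.06, 0.04])
        labels = oc.label_windows(p_right, np.ones(3), alpha=0.05, correction="none")
        assert list(labels) == ["depleted", "unchanged", "depleted"]

    def test_low_coverage_label_wins(self):
        labels = oc.label_windows(
            np.array([0.001, 0.5]), np.ones(2), low_mask=np.array([True, False])
        )
        assert list(labels) == ["low_coverage", "unchanged"]


class TestRunningMean:
    def test_shrinking_edges(self):
        np.testing.assert_allclose(
            oc.running_mean(np.array([0.0, 0, 3, 0, 0]), 3), [0, 1, 1, 1, 0]
        )

    def test_span_one_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_allclose(oc.running_mean(x, 1), x)

    def test_constant_preserved(self):
        np.testing.assert_allclose(oc.running_mean(np.full(9, 2.5), 5), np.full(9, 2.5))

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            oc.running_mean(np.zeros(5), 4)

    def test_respects_chromosome_boundaries(self):
        values = np.array([0.0, 0, 3, 0, 0])
        chroms = np.array(["a", "a", "a", "b", "b"])
        out = oc.running_mean(values, 3, chroms)
        np.testing.assert_allclose(out, [0, 1, 1.5, 0, 0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    shift=st.floats(min_value=-3, max_value=3, allow_nan=False),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_pvalues_invariant_to_global_shift(shift, seed):
    """Centering makes the statistic invariant to any uniform offset of Q."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=400)
    mask = np.zeros(400, dtype=bool)
    c1 = oc.center(q, mask)
    c2 = oc.center(q + shift, mask)
    np.testing.assert_allclose(c1, c2, atol=1e-9)


def test_select_inert_windows_excludes_expressed_genes(gene_frame, small_index):
    grid = oc.tile_genome(small_index, 10_000)
    inert = oc.select_inert_windows(grid, gene_frame)
    frame = grid.to_frame().assign(inert=inert)
    overlapping = frame[
        (frame["chrom"] == "chr1") & (frame["start"] < 30_000) & (frame["end"] > 20_000)
    ]
    assert not overlapping["inert"].any()
    desert = frame[(frame["chrom"] == "chr2")]
    assert desert["inert"].all()
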