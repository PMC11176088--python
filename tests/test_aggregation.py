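"""Reductions, bilinear regularization, and the three pileups."""

import numpy as np
import pandas as pd
import pytest

import hicpile as hp
from hicpile.aggregation import _bilinear_resample
from hicpile.pairs import ANCHOR_COLS

from conftest import BINSIZE


def as_submatrix_array(stacks, genome=None, binsize=BINSIZE):
    """Wrap a (n, f, r, c) array in a SubmatrixArray with dummy interactions."""
    stacks = np.asarray(stacks, dtype=float)
    n = stacks.shape[0]
    genome = genome or hp.ChromSizes([("c", 10_000_000)])
    df = pd.DataFrame(
        [("c", i * binsize, (i + 1) * binsize, "c", i * binsize, (i + 1) * binsize) for i in range(n)],
        columns=ANCHOR_COLS,
    )
    lo = np.arange(n, dtype=np.int64)
    return hp.SubmatrixArray(
        stacks, hp.BinnedPairSet(df, genome, binsize, lo, lo + 1, lo, lo + 1),
        [f"f{j}" for j in range(stacks.shape[1])], {},
    )


class TestAggMatrices:
    def test_sum_by_hand(self):
        arr = as_submatrix_array([[[[1, 2], [3, 4]]], [[[5, 6], [7, 8]]]])
        out = hp.agg_matrices(arr, by="both", fn="sum")
        assert out.values.tolist() == [[6, 8], [10, 12]]
        assert (out.n_contributing == 2).all()

    def test_single_matrix_identity(self):
        m = [[[1.5, 2.5], [3.5, 4.5]]]
        for fn in ("sum", "mean", "median"):
            out = hp.agg_matrices(as_submatrix_array([m]), by="both", fn=fn)
            assert out.values.tolist() == m[0]

    def test_missing_aware_mean(self):
        a = [[[1.0, np.nan], [3.0, 4.0]]]
        b = [[[5.0, 6.0], [7.0, 8.0]]]
        out = hp.agg_matrices(as_submatrix_array([a, b]), by="both", fn="mean")
        assert out.values[0, 1] == 6.0
        assert out.n_contributing[0, 1] == 1
        assert out.values[0, 0] == 3.0

    def test_by_interactions_and_files_shapes(self):
        stacks = np.arange(2 * 3 * 2 * 2).reshape(2, 3, 2, 2)
        arr = as_submatrix_array(stacks)
        per_file = hp.agg_matrices(arr, by="interactions", fn="mean")
        assert len(per_file) == 3
        np.testing.assert_array_equal(per_file[0].values, stacks[:, 0].mean(axis=0))
        per_interaction = hp.agg_matrices(arr, by="files", fn="sum")
        assert len(per_interaction) == 2
        np.testing.assert_array_equal(per_interaction[1].values, stacks[1].sum(axis=0))

    def test_sum_equals_accumulation_loop(self):
        rng = np.random.default_rng(0)
        stacks = rng.poisson(3.0, (6, 2, 4, 4)).astype(float)
        out = hp.agg_matrices(as_submatrix_array(stacks), by="both", fn="sum")
        acc = np.zeros((4, 4))
        for i in range(6):
            for j in range(2):
                acc += stacks[i, j]
        np.testing.assert_array_equal(out.values, acc)

    def test_jagged_input_directed_to_regularize(self, store, genome2):
        lo = np.array([100, 200])
        hi = lo + np.array([3, 5])
        df = pd.DataFrame(
            [("chr1", 0, 1, "chr1", 0, 1), ("chr1", 0, 1, "chr1", 0, 1)], columns=ANCHOR_COLS
        )
        jag = hp.pull_submatrices(
            [store], hp.BinnedPairSet(df, genome2, BINSIZE, lo, hi, lo, hi)
        )
        with pytest.raises(TypeError, match="regularize"):
            hp.agg_matrices(jag)


def bilinear_oracle(mat, ndim):
    """Independent nearest-4-neighbour bilinear interpolation on cell centers."""
    mat = np.asarray(mat, dtype=float)
    r, c = mat.shape
    out = np.zeros((ndim, ndim))
    for a in range(ndim):
        for b in range(ndim):
            y = np.clip((a + 0.5) / ndim, 0.5 / r, (r - 0.5) / r) * r - 0.5
            x = np.clip((b + 0.5) / ndim, 0.5 / c, (c - 0.5) / c) * c - 0.5
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, r - 1), min(x0 + 1, c - 1)
            fy, fx = y - y0, x - x0
            out[a, b] = (
                mat[y0, x0] * (1 - fy) * (1 - fx)
                + mat[y1, x0] * fy * (1 - fx)
                + mat[y0, x1] * (1 - fy) * fx
                + mat[y1, x1] * fy * fx
            )
    return out


class TestRegularize:
    def test_identity_at_native_size(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(5.0, (7, 7)).astype(float)
        np.testing.assert_array_equal(_bilinear_resample(m, 7), m)

    def test_two_by_two_to_three_by_three(self):
        out = _bilinear_resample(np.array([[0.0, 2.0], [2.0, 4.0]]), 3)
        np.testing.assert_allclose(out, [[0, 1, 2], [1, 2, 3], [2, 3, 4]], atol=1e-12)

    @pytest.mark.parametrize("shape,ndim", [((3, 3), 8), ((5, 7), 4), ((2, 9), 6), ((13, 13), 5)])
    def test_agrees_with_independent_oracle(self, shape, ndim):
        rng = np.random.default_rng(2)
        m = rng.poisson(4.0, shape).astype(float)
        np.testing.assert_allclose(_bilinear_resample(m, ndim), bilinear_oracle(m, ndim), rtol=1e-12, atol=1e-12)

    def test_scale_to_sum(self, store, genome2):
        lo = np.array([100, 200])
        hi = lo + np.array([4, 7])
        df = pd.DataFrame(
            [("chr1", 0, 1, "chr1", 0, 1)] * 2, columns=ANCHOR_COLS
        )
        jag = hp.pull_submatrices(
            [store], hp.BinnedPairSet(df, genome2, BINSIZE, lo, hi, lo, hi)
        )
        reg = hp.regularize(jag, hp.RegularizeSpec(ndim=10, scale_to_sum=True))
        for i in range(2):
            src_sum = jag.matrix(i, 0).sum()
            np.testing.assert_allclose(np.asarray(reg.counts)[i, 0].sum(), src_sum, rtol=1e-9)

    def test_degenerate_rows_dropped(self, store, genome2):
        lo = np.array([100, 200])
        hi = np.array([101, 204])  # a 1x1 and a 4x4
        df = pd.DataFrame([("chr1", 0, 1, "chr1", 0, 1)] * 2, columns=ANCHOR_COLS)
        jag = hp.pull_submatrices(
            [store], hp.BinnedPairSet(df, genome2, BINSIZE, lo, hi, lo, hi)
        )
        reg = hp.regularize(jag, 5)
        assert len(reg) == 1

    def test_ndim_below_two_rejected(self):
        with pytest.raises(ValueError, match="ndim"):
            hp.RegularizeSpec(ndim=1)


class TestPileupPixels:
    def test_apa_peaks_at_center(self, store, truth):
        mats = hp.pileup_pixels([store], truth.loop_pixels_bp(), BINSIZE, buffer_bins=5)
        v = mats[0].values
        assert np.unravel_index(np.nanargmax(v), v.shape) == (5, 5)

    def test_center_equals_mean_of_pixel_pulls(self, store, truth):
        pairs = truth.loop_pixels_bp()
        mats = hp.pileup_pixels([store], pairs, BINSIZE, buffer_bins=5)
        binned = hp.snap_to_bins(pairs, BINSIZE)
        expanded, _ = hp.expand_pixels(binned, 5).drop_invalid()
        survivors, _ = hp.remove_short_pairs(expanded, padding_bins=5)
        px = hp.pull_pixels(
            [store],
            hp.BinnedPairSet(
                survivors.df, survivors.chromsizes, BINSIZE,
                survivors.bin1, survivors.bin1 + 1, survivors.bin2, survivors.bin2 + 1,
            ),
        )
        assert mats[0].values[5, 5] == px.counts[:, 0].mean()

    def test_single_pair_identity(self, store, truth, genome2):
        df = pd.DataFrame(
            [("chr1", 100 * BINSIZE, 101 * BINSIZE, "chr1", 140 * BINSIZE, 141 * BINSIZE)],
            columns=ANCHOR_COLS,
        )
        mats = hp.pileup_pixels([store], hp.PairSet(df, genome2), BINSIZE, buffer_bins=3)
        direct = store.fetch((97, 104), (137, 144)).values
        np.testing.assert_array_equal(mats[0].values, direct)

    def test_empty_pairs_error(self, store, genome2):
        empty = hp.PairSet(pd.DataFrame(columns=ANCHOR_COLS), genome2)
        with pytest.raises(ValueError):
            hp.pileup_pixels([store], empty, BINSIZE)

    def test_order_invariance(self, store, truth):
        pairs = truth.loop_pixels_bp()
        perm = np.random.default_rng(3).permutation(len(pairs))
        a = hp.pileup_pixels([store], pairs, BINSIZE)[0].values
        b = hp.pileup_pixels([store], pairs.take(perm), BINSIZE)[0].values
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestPileupDomains:
    def test_window_expansion_by_hand(self, store, genome2):
        # buffer_frac 0.5 on a 100 kb domain -> 200 kb window centred on it
        doms = [hp.GenomicRange("chr1", 2_000_000, 2_100_000)]
        mats = hp.pileup_domains([store], doms, BINSIZE, buffer_frac=0.5, ndim=20,
                                 per_matrix_norm="none")
        direct = store.fetch((195, 215), (195, 215)).values.astype(float)
        np.testing.assert_allclose(mats[0].values, _bilinear_resample(direct, 20), rtol=1e-12)

    def test_native_size_identity_chain(self, store, genome2):
        doms = [hp.GenomicRange("chr1", 2_000_000, 2_200_000)]  # 20 bins
        mats = hp.pileup_domains([store], doms, BINSIZE, buffer_frac=0.0, ndim=20,
                                 per_matrix_norm="none")
        direct = store.fetch((200, 220), (200, 220)).values
        np.testing.assert_array_equal(mats[0].values, direct)

    def test_planted_tads_enriched_inside(self, store, truth):
        doms = [
            hp.GenomicRange(t.chrom, t.start_bin * BINSIZE, t.end_bin * BINSIZE)
            for t in truth.tads
        ]
        mats = hp.pileup_domains([store], doms, BINSIZE, buffer_frac=0.5, ndim=40)
        v = mats[0].values
        # window spans 2x the domain: the domain occupies the central half
        inside = v[15:25, 15:25].mean()
        corner = v[:8, 32:].mean()  # off-diagonal flank corner
        assert inside > corner

    def test_all_dropped_is_error(self, store, genome2):
        doms = [hp.GenomicRange("chr1", 0, 100_000)]  # flank would go below 0
        with pytest.raises(ValueError, match="outside"):
            hp.pileup_domains([store], doms, BINSIZE, buffer_frac=1.0)


class TestPileupBoundaries:
    def test_window_geometry(self, store):
        mats = hp.pileup_boundaries([store], [("chr1", 1_000_000)], BINSIZE, flank_bp=100_000)
        assert mats[0].shape == (21, 21)

    def test_single_boundary_identity(self, store):
        mats = hp.pileup_boundaries([store], [("chr1", 1_000_000)], BINSIZE, flank_bp=100_000)
        direct = store.fetch((90, 111), (90, 111)).values
        np.testing.assert_array_equal(mats[0].values, direct)

    def test_tad_edges_show_insulation(self, store, truth):
        """Intra-TAD quadrants beat the cross-boundary quadrant."""
        edges = [("chr1", 230 * BINSIZE)]  # boundary between two planted TADs
        mats = hp.pileup_boundaries([store], edges, BINSIZE, flank_bp=150_000)
        v = mats[0].values
        n = v.shape[0]
        c = n // 2
        upper_left = v[:c, :c][np.triu_indices(c, 1)].mean()
        lower_right = v[c + 1 :, c + 1 :][np.triu_indices(n - c - 1, 1)].mean()
        inter = v[:c, c + 1 :].mean()
        assert upper_left > inter and lower_right > inter

    def test_flank_below_binsize_rejected(self, store):
        with pytest.raises(ValueError, match="flank"):
            hp.pileup_boundaries([store], [("chr1", 1_000_000)], BINSIZE, flank_bp=5_000)
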