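"""Block planning, pixel/submatrix pulling, and HDF5 persistence."""

import numpy as np
import pandas as pd
import pytest

import hicpile as hp
from hicpile.extraction import LAYOUT_VERSION
from hicpile.pairs import ANCHOR_COLS

from conftest import BINSIZE


def random_pixel_pairs(truth, n, rng, min_gap=0):
    """Random intra-chromosomal single-pixel queries in bp coordinates."""
    rows = []
    for _ in range(n):
        chrom = rng.choice(truth.chromsizes.names)
        nb = truth.chromsizes.n_bins(BINSIZE, chrom)
        i = int(rng.integers(0, nb))
        j = int(rng.integers(min(i + min_gap, nb - 1), nb))
        rows.append(
            (chrom, i * BINSIZE, (i + 1) * BINSIZE, chrom, j * BINSIZE, (j + 1) * BINSIZE)
        )
    df = pd.DataFrame(rows, columns=ANCHOR_COLS)
    return hp.snap_to_bins(hp.PairSet(df, truth.chromsizes), BINSIZE)


class TestPlanBlocks:
    def _pixels_at(self, genome, positions_bp, binsize=BINSIZE):
        rows = [
            ("chr1", p, p + binsize, "chr1", p, p + binsize) for p in positions_bp
        ]
        return hp.snap_to_bins(hp.PairSet(pd.DataFrame(rows, columns=ANCHOR_COLS), genome), binsize)

    def test_grouping_by_tile(self, genome2, store):
        pairs = self._pixels_at(genome2, [100_000, 200_000, 4_800_000])
        plan = hp.plan_blocks(pairs, [store], hp.ExtractionConfig(block_span_bp=1_000_000))
        assert plan.n_blocks == 2
        sizes = sorted(len(b.members) for b in plan.blocks)
        assert sizes == [1, 2]

    def test_singleton(self, genome2, store):
        pairs = self._pixels_at(genome2, [100_000])
        assert hp.plan_blocks(pairs, [store]).n_blocks == 1

    def test_footprint_larger_than_span_errors(self, genome2, store):
        pairs = hp.expand_pixels(self._pixels_at(genome2, [1_000_000]), 2)  # 5x5 at 10 kb
        with pytest.raises(ValueError, match="block_span_bp"):
            hp.plan_blocks(pairs, [store], hp.ExtractionConfig(block_span_bp=40_000))

    def test_every_query_covered_once(self, truth, store):
        rng = np.random.default_rng(0)
        pairs = random_pixel_pairs(truth, 100, rng)
        plan = hp.plan_blocks(pairs, [store], hp.ExtractionConfig(block_span_bp=500_000))
        seen = np.concatenate([b.members for b in plan.blocks])
        assert sorted(seen.tolist()) == list(range(100))
        for b in plan.blocks:
            assert (pairs.row_start[b.members] >= b.rows[0]).all()
            assert (pairs.row_stop[b.members] <= b.rows[1]).all()
            assert (pairs.col_start[b.members] >= b.cols[0]).all()
            assert (pairs.col_stop[b.members] <= b.cols[1]).all()


class TestPullPixels:
    def test_matches_dense_oracle(self, store, truth):
        rng = np.random.default_rng(1)
        pairs = random_pixel_pairs(truth, 200, rng)
        pm = hp.pull_pixels([store], pairs)
        offs = truth.chromsizes.offsets(BINSIZE)
        for q in range(len(pairs)):
            chrom = pairs.df.chrom1[q]
            i = pairs.bin1[q] - offs[chrom]
            j = pairs.bin2[q] - offs[chrom]
            assert pm.counts[q, 0] == truth.counts[chrom][i, j]

    def test_balanced_matches_dense_oracle(self, store, truth):
        rng = np.random.default_rng(2)
        pairs = random_pixel_pairs(truth, 100, rng)
        pm = hp.pull_pixels([store], pairs, hp.ExtractionConfig(normalization="balanced"))
        offs = truth.chromsizes.offsets(BINSIZE)
        w = truth.weights
        for q in range(len(pairs)):
            chrom = pairs.df.chrom1[q]
            i, j = pairs.bin1[q] - offs[chrom], pairs.bin2[q] - offs[chrom]
            expected = truth.counts[chrom][i, j] * w[pairs.bin1[q]] * w[pairs.bin2[q]]
            np.testing.assert_allclose(pm.counts[q, 0], expected, rtol=1e-9)

    def test_block_span_invariance_and_order(self, store, truth):
        rng = np.random.default_rng(3)
        pairs = random_pixel_pairs(truth, 150, rng)
        base = hp.pull_pixels([store], pairs, hp.ExtractionConfig(block_span_bp=BINSIZE))
        for span in (100_000, 10_000_000):
            alt = hp.pull_pixels([store], pairs, hp.ExtractionConfig(block_span_bp=span))
            np.testing.assert_array_equal(base.counts, alt.counts)
        perm = rng.permutation(len(pairs))
        shuffled = hp.pull_pixels([store], pairs.take(perm))
        np.testing.assert_array_equal(shuffled.counts[np.argsort(perm)], base.counts)

    def test_duplicate_file_columns_equal(self, store, truth):
        rng = np.random.default_rng(4)
        pairs = random_pixel_pairs(truth, 30, rng)
        pm = hp.pull_pixels([store, store], pairs)
        assert pm.counts.shape == (30, 2)
        np.testing.assert_array_equal(pm.counts[:, 0], pm.counts[:, 1])
        assert pm.file_labels[0] != pm.file_labels[1]

    def test_multi_file_equals_column_stack(self, store, truth, plain_sim, genome2):
        rng = np.random.default_rng(5)
        pairs = random_pixel_pairs(truth, 20, rng)
        single = hp.pull_pixels([store], pairs).counts
        both = hp.pull_pixels([store, store], pairs).counts
        np.testing.assert_array_equal(both, np.column_stack([single[:, 0], single[:, 0]]))

    def test_binsize_mismatch_rejected(self, plain_sim, truth):
        other_store, other_truth = plain_sim
        pairs = random_pixel_pairs(other_truth, 5, np.random.default_rng(6))
        bad = hp.snap_to_bins(hp.PairSet(pairs.df, other_truth.chromsizes), 20_000)
        with pytest.raises(ValueError, match="resolution"):
            hp.pull_pixels([other_store], bad)

    def test_multi_bin_anchor_rejected(self, store, truth):
        pairs = random_pixel_pairs(truth, 5, np.random.default_rng(7), min_gap=20)
        wide = hp.expand_pixels(pairs, 1)
        with pytest.raises(ValueError, match="single-bin"):
            hp.pull_pixels([store], wide)


class TestPullSubmatrices:
    def test_center_equals_pixel_value(self, store, truth):
        pairs = random_pixel_pairs(truth, 40, np.random.default_rng(8), min_gap=30)
        px = hp.pull_pixels([store], pairs)
        expanded = hp.expand_pixels(pairs, 2)
        kept = np.flatnonzero(expanded.valid)
        sub, _ = expanded.drop_invalid()
        arr = hp.pull_submatrices([store], sub)
        assert isinstance(arr, hp.SubmatrixArray)
        centers = np.asarray(arr.counts)[:, 0, 2, 2]
        np.testing.assert_array_equal(centers, px.counts[kept, 0])

    def test_each_submatrix_equals_fetch_block(self, store, truth):
        pairs = random_pixel_pairs(truth, 20, np.random.default_rng(9), min_gap=30)
        sub, _ = hp.expand_pixels(pairs, 3).drop_invalid()
        arr = hp.pull_submatrices([store], sub, hp.ExtractionConfig(block_span_bp=200_000))
        for q in range(len(sub)):
            direct = store.fetch(
                (sub.row_start[q], sub.row_stop[q]), (sub.col_start[q], sub.col_stop[q])
            ).values
            np.testing.assert_array_equal(arr.matrix(q, 0), direct)

    def _jagged(self, genome, widths, start_bins):
        rows = [
            ("chr1", s * BINSIZE, (s + w) * BINSIZE, "chr1", s * BINSIZE, (s + w) * BINSIZE)
            for s, w in zip(start_bins, widths)
        ]
        df = pd.DataFrame(rows, columns=ANCHOR_COLS)
        lo = np.asarray(start_bins, dtype=np.int64)
        hi = lo + np.asarray(widths, dtype=np.int64)
        return hp.BinnedPairSet(df, genome, BINSIZE, lo, hi, lo, hi)

    def test_mixed_widths_give_jagged_dims(self, store, genome2):
        pairs = self._jagged(genome2, [3, 5], [100, 200])
        arr = hp.pull_submatrices([store], pairs)
        assert isinstance(arr, hp.JaggedSubmatrixArray)
        assert arr.dims.tolist() == [[3, 3], [5, 5]]
        assert arr.offsets[-1] == 3 * 3 + 5 * 5

    def test_square_through_jagged_path_matches_regular(self, store, truth, genome2):
        pairs = random_pixel_pairs(truth, 10, np.random.default_rng(10), min_gap=30)
        sub, _ = hp.expand_pixels(pairs, 2).drop_invalid()
        regular = hp.pull_submatrices([store], sub)
        # same footprints expressed as jagged queries (force via odd one out, then subset)
        jag = self._jagged(genome2, [5] * len(sub) + [3], list(range(60, 60 + 12 * len(sub), 12)) + [450])
        lo_r, hi_r = sub.row_start, sub.row_stop
        jag_same = hp.BinnedPairSet(
            sub.df, genome2, BINSIZE, lo_r, hi_r, sub.col_start, sub.col_stop
        )
        forced = hp.pull_submatrices([store], hp.BinnedPairSet(
            pd.concat([jag_same.df, jag.df.iloc[[-1]]], ignore_index=True),
            genome2, BINSIZE,
            np.concatenate([jag_same.row_start, jag.row_start[-1:]]),
            np.concatenate([jag_same.row_stop, jag.row_stop[-1:]]),
            np.concatenate([jag_same.col_start, jag.col_start[-1:]]),
            np.concatenate([jag_same.col_stop, jag.col_stop[-1:]]),
        ))
        assert isinstance(forced, hp.JaggedSubmatrixArray)
        for q in range(len(sub)):
            np.testing.assert_array_equal(forced.matrix(q, 0), regular.matrix(q, 0))

    def test_invalid_footprints_rejected(self, store, truth):
        pairs = random_pixel_pairs(truth, 10, np.random.default_rng(11))
        wide = hp.expand_pixels(pairs, 5)
        if wide.valid.all():  # ensure at least one out-of-range footprint
            wide.valid[0] = False
        with pytest.raises(ValueError, match="drop_invalid"):
            hp.pull_submatrices([store], wide)


class TestMemoryContract:
    def test_peak_fetch_bounded_by_block_not_query_count(self, store, truth, monkeypatch):
        """Fetched dense rectangles stay block-sized however many queries run."""
        fetched_cells = []
        orig = hp.ContactStore.fetch

        def spy(self, *a, **k):
            blk = orig(self, *a, **k)
            fetched_cells.append(blk.values.size)
            return blk

        monkeypatch.setattr(hp.ContactStore, "fetch", spy)
        pairs = random_pixel_pairs(truth, 400, np.random.default_rng(12))
        span_bins = 50
        hp.pull_pixels([store], pairs, hp.ExtractionConfig(block_span_bp=span_bins * BINSIZE))
        assert len(fetched_cells) > 1
        # each fetch covers at most one (enlarged) tile, never the query set
        assert max(fetched_cells) <= (span_bins + 1) ** 2


class TestPersistence:
    def test_pixel_matrix_round_trip_bit_exact(self, store, truth, tmp_path):
        pairs = random_pixel_pairs(truth, 25, np.random.default_rng(13))
        pm = hp.pull_pixels([store], pairs)
        hp.persist(pm, tmp_path / "pm.h5")
        back = hp.load(tmp_path / "pm.h5")
        np.testing.assert_array_equal(np.asarray(back.counts), pm.counts)
        pd.testing.assert_frame_equal(back.interactions.df, pm.interactions.df)
        assert back.file_labels == pm.file_labels
        assert back.metadata == pm.metadata
        back.close()

    def test_loaded_counts_are_lazy(self, store, truth, tmp_path):
        import h5py

        pairs = random_pixel_pairs(truth, 25, np.random.default_rng(14))
        hp.persist(hp.pull_pixels([store], pairs), tmp_path / "pm.h5")
        back = hp.load(tmp_path / "pm.h5")
        assert isinstance(back.counts, h5py.Dataset)  # not read into memory
        assert back.counts[3, 0] == np.asarray(back.counts)[3, 0]
        back.close()

    def test_slice_commutes_with_round_trip(self, store, truth, tmp_path):
        pairs = random_pixel_pairs(truth, 30, np.random.default_rng(15))
        pm = hp.pull_pixels([store], pairs)
        hp.persist(pm, tmp_path / "pm.h5")
        back = hp.load(tmp_path / "pm.h5")
        np.testing.assert_array_equal(np.asarray(back[10:20].counts), pm[10:20].counts)
        back.close()

    def test_submatrix_and_jagged_round_trip(self, store, truth, genome2, tmp_path):
        pairs = random_pixel_pairs(truth, 10, np.random.default_rng(16), min_gap=30)
        sub, _ = hp.expand_pixels(pairs, 2).drop_invalid()
        arr = hp.pull_submatrices([store], sub)
        hp.persist(arr, tmp_path / "sub.h5")
        back = hp.load(tmp_path / "sub.h5")
        np.testing.assert_array_equal(np.asarray(back.counts), np.asarray(arr.counts))
        back.close()

        lo = np.array([100, 200])
        hi = lo + np.array([3, 5])
        df = sub.df.iloc[:2].reset_index(drop=True)
        jag = hp.pull_submatrices(
            [store], hp.BinnedPairSet(df, genome2, BINSIZE, lo, hi, lo, hi)
        )
        hp.persist(jag, tmp_path / "jag.h5")
        back = hp.load(tmp_path / "jag.h5")
        for i in range(2):
            np.testing.assert_array_equal(back.matrix(i, 0), jag.matrix(i, 0))
        back.close()

    def test_layout_version_mismatch(self, store, truth, tmp_path):
        import h5py

        pairs = random_pixel_pairs(truth, 5, np.random.default_rng(17))
        hp.persist(hp.pull_pixels([store], pairs), tmp_path / "pm.h5")
        with h5py.File(tmp_path / "pm.h5", "a") as h5:
            h5.attrs["layout_version"] = LAYOUT_VERSION + 1
        with pytest.raises(ValueError, match="layout version"):
            hp.load(tmp_path / "pm.h5")
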