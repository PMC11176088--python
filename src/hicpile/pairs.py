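"""Paired genomic anchors and bin-grid arithmetic.

:class:`PairSet` is the loop/domain call abstraction: an ordered table of
anchor pairs with arbitrary per-pair metadata columns. :class:`BinnedPairSet`
adds a bin grid: every anchor is snapped to whole bins and carries a square
(or rectangular, for the jagged path) footprint expressed in genome-wide bin
ids. Operations here never reorder surviving pairs and carry metadata
through unchanged.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import ChromSizes

logger = logging.getLogger(__name__)

ANCHOR_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]

__all__ = [
    "PairSet",
    "BinnedPairSet",
    "snap_to_bins",
    "expand_pixels",
    "remove_short_pairs",
]


class PairSet:
    """Ordered collection of paired genomic anchors with metadata.

    Parameters
    ----------
    df:
        DataFrame with at least the six BEDPE anchor columns
        (``chrom1, start1, end1, chrom2, start2, end2``); any further
        columns are per-pair metadata.
    chromsizes:
        Optional genome the anchors live on; required for binning.
    source:
        Optional per-pair source label (e.g. which replicate file a loop
        call came from).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        chromsizes: Optional[ChromSizes] = None,
        source: Optional[Sequence[str]] = None,
    ):
        missing = [c for c in ANCHOR_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"pair table missing anchor columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.chromsizes = chromsizes
        if source is not None:
            source = np.asarray(source, dtype=object)
            if len(source) != len(self.df):
                raise ValueError("source labels length mismatch")
        self.source = source

    def __len__(self) -> int:
        return len(self.df)

    @property
    def metadata_columns(self) -> List[str]:
        return [c for c in self.df.columns if c not in ANCHOR_COLS]

    @property
    def metadata(self) -> pd.DataFrame:
        return self.df[self.metadata_columns]

    def take(self, idx) -> "PairSet":
        idx = np.asarray(idx)
        src = self.source[idx] if self.source is not None else None
        return PairSet(self.df.iloc[idx], self.chromsizes, src)

    @staticmethod
    def concat(pair_sets: Iterable["PairSet"], labels: Optional[Sequence[str]] = None) -> "PairSet":
        """Stack pair sets, tagging each pair with its source label.

        Labels default to existing per-set sources, else ``"list<i>"``.
        """
        pair_sets = list(pair_sets)
        if not pair_sets:
            raise ValueError("nothing to concatenate")
        dfs, sources = [], []
        for i, ps in enumerate(pair_sets):
            dfs.append(ps.df)
            if ps.source is not None:
                sources.append(np.asarray(ps.source, dtype=object))
            else:
                label = labels[i] if labels is not None else f"list{i}"
                sources.append(np.full(len(ps), label, dtype=object))
        df = pd.concat(dfs, ignore_index=True, sort=False)
        return PairSet(df, pair_sets[0].chromsizes, np.concatenate(sources) if len(df) else None)

    def to_bedpe(self, path) -> None:
        """Write as tab-separated BEDPE (anchor columns then metadata)."""
        cols = ANCHOR_COLS + self.metadata_columns
        out = self.df[cols]
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(cols) + "\n")
            out.to_csv(fh, sep="\t", header=False, index=False)

    def __repr__(self) -> str:
        return f"{type(self).__name__}(n={len(self)}, metadata={self.metadata_columns})"


class BinnedPairSet(PairSet):
    """A PairSet snapped to a bin grid, with per-pair footprints.

    Footprints are half-open genome-wide bin intervals: rows follow
    anchor1, columns anchor2. For single-pixel pairs each interval has
    length 1. ``valid`` flags footprints that fit inside their chromosome;
    out-of-range footprints are never clipped, only flagged.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        chromsizes: ChromSizes,
        binsize: int,
        row_start,
        row_stop,
        col_start,
        col_stop,
        valid=None,
        source=None,
    ):
        super().__init__(df, chromsizes, source)
        if chromsizes is None:
            raise ValueError("BinnedPairSet requires chromsizes")
        self.binsize = int(binsize)
        n = len(self.df)
        self.row_start = np.asarray(row_start, dtype=np.int64).reshape(n)
        self.row_stop = np.asarray(row_stop, dtype=np.int64).reshape(n)
        self.col_start = np.asarray(col_start, dtype=np.int64).reshape(n)
        self.col_stop = np.asarray(col_stop, dtype=np.int64).reshape(n)
        self.valid = (
            np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool).reshape(n)
        )

    # bin1/bin2 are the anchor pixels (footprint-independent centers)
    @property
    def bin1(self) -> np.ndarray:
        return (self.row_start + self.row_stop - 1) // 2

    @property
    def bin2(self) -> np.ndarray:
        return (self.col_start + self.col_stop - 1) // 2

    @property
    def footprint_shapes(self) -> np.ndarray:
        """(n, 2) array of (rows, cols) footprint sizes in bins."""
        return np.stack(
            [self.row_stop - self.row_start, self.col_stop - self.col_start], axis=1
        )

    def is_intra(self) -> np.ndarray:
        return (self.df["chrom1"] == self.df["chrom2"]).to_numpy()

    def take(self, idx) -> "BinnedPairSet":
        idx = np.asarray(idx)
        src = self.source[idx] if self.source is not None else None
        return BinnedPairSet(
            self.df.iloc[idx],
            self.chromsizes,
            self.binsize,
            self.row_start[idx],
            self.row_stop[idx],
            self.col_start[idx],
            self.col_stop[idx],
            self.valid[idx],
            src,
        )

    def drop_invalid(self):
        """Return (subset of in-range pairs, number dropped)."""
        keep = np.flatnonzero(self.valid)
        n_dropped = len(self) - len(keep)
        if n_dropped:
            logger.info("dropping %d pairs with out-of-range footprints", n_dropped)
        return self.take(keep), n_dropped


def snap_to_bins(
    pairs: PairSet,
    binsize_bp: int,
    anchor_point: str = "center",
    chromsizes: Optional[ChromSizes] = None,
) -> BinnedPairSet:
    """Snap each anchor to the single bin containing its representative point.

    ``anchor_point`` selects the representative base pair: the anchor's
    start, its midpoint (floor of ``(start+end)/2``), or its last base
    (``end - 1``). Intra-chromosomal pairs are reoriented so bin1 <= bin2.
    Idempotent: snapping an already-snapped set changes nothing.
    """
    if binsize_bp <= 0:
        raise ValueError("binsize_bp must be positive")
    if anchor_point not in ("start", "center", "end"):
        raise ValueError(f"unknown anchor_point {anchor_point!r}")
    genome = chromsizes or pairs.chromsizes
    if genome is None:
        raise ValueError("chromsizes required to snap (pass chromsizes=)")

    df = pairs.df.copy()

    def rep_point(start, end):
        if anchor_point == "start":
            return start
        if anchor_point == "end":
            return end - 1
        return (start + end) // 2

    offs = genome.offsets(binsize_bp)
    bins = {}
    for side in ("1", "2"):
        chrom = df[f"chrom{side}"].to_numpy()
        p = rep_point(
            df[f"start{side}"].to_numpy(np.int64), df[f"end{side}"].to_numpy(np.int64)
        )
        k = p // binsize_bp
        gw = np.empty(len(df), dtype=np.int64)
        for i, c in enumerate(chrom):
            nb = genome.n_bins(binsize_bp, c)
            if not 0 <= k[i] < nb:
                raise ValueError(
                    f"pair {i}: snapped bin {k[i]} beyond {c!r} ({nb} bins at {binsize_bp} bp)"
                )
            gw[i] = offs[c] + k[i]
        bins[side] = gw
        df[f"start{side}"] = k * binsize_bp
        df[f"end{side}"] = np.minimum((k + 1) * binsize_bp, np.array([genome[c] for c in chrom]))

    b1, b2 = bins["1"], bins["2"]
    # canonical orientation on the bin grid for intra-chromosomal pairs
    intra = (df["chrom1"] == df["chrom2"]).to_numpy()
    flip = intra & (b1 > b2)
    if flip.any():
        b1_new = np.where(flip, b2, b1)
        b2_new = np.where(flip, b1, b2)
        for col in ("chrom", "start", "end"):
            a, b = df[f"{col}1"].to_numpy(), df[f"{col}2"].to_numpy()
            df[f"{col}1"] = np.where(flip, b, a)
            df[f"{col}2"] = np.where(flip, a, b)
        b1, b2 = b1_new, b2_new

    return BinnedPairSet(
        df, genome, binsize_bp, b1, b1 + 1, b2, b2 + 1, source=pairs.source
    )


def expand_pixels(pairs: BinnedPairSet, buffer_bins: int) -> BinnedPairSet:
    """Grow each single-bin anchor to a (2*buffer+1)-bin square footprint.

    Footprints are never clipped: pairs whose footprint would leave the
    chromosome are flagged invalid for the caller to drop.
    """
    if buffer_bins < 0:
        raise ValueError("buffer_bins must be non-negative")
    if not np.all(pairs.footprint_shapes == 1):
        raise ValueError("expand_pixels requires single-bin anchors (snap first)")
    b1, b2 = pairs.bin1, pairs.bin2
    rs, re = b1 - buffer_bins, b1 + buffer_bins + 1
    cs, ce = b2 - buffer_bins, b2 + buffer_bins + 1

    genome, binsize = pairs.chromsizes, pairs.binsize
    spans = {c: genome.bin_span(c, binsize) for c in genome.names}
    lo1 = np.array([spans[c][0] for c in pairs.df["chrom1"]])
    hi1 = np.array([spans[c][1] for c in pairs.df["chrom1"]])
    lo2 = np.array([spans[c][0] for c in pairs.df["chrom2"]])
    hi2 = np.array([spans[c][1] for c in pairs.df["chrom2"]])
    valid = (rs >= lo1) & (re <= hi1) & (cs >= lo2) & (ce <= hi2) & pairs.valid

    return BinnedPairSet(
        pairs.df, genome, binsize, rs, re, cs, ce, valid, pairs.source
    )


def remove_short_pairs(pairs: BinnedPairSet, padding_bins: int = 0, padding_bp: int | None = None):
    """Drop intra-chromosomal pairs whose footprint touches the diagonal band.

    A pair survives iff the gap between its footprint and the diagonal —
    lowest column bin minus highest row bin — is at least ``padding_bins``.
    Inter-chromosomal pairs always survive. When ``padding_bp`` is given it
    overrides ``padding_bins`` via ceiling division by the bin size (the
    diagonal is a bin-grid object, so padding is measured in bins).

    Returns ``(survivors, n_kept)``; survivor order is input order.
    """
    if padding_bp is not None:
        padding_bins = -(-int(padding_bp) // pairs.binsize)
    if padding_bins < 0:
        raise ValueError("padding must be non-negative")
    gap = pairs.col_start - (pairs.row_stop - 1)
    keep = ~pairs.is_intra() | (gap >= padding_bins)
    survivors = pairs.take(np.flatnonzero(keep))
    n_kept = len(survivors)
    if n_kept < len(pairs):
        logger.info(
            "remove_short_pairs: dropped %d of %d pairs (padding=%d bins)",
            len(pairs) - n_kept, len(pairs), padding_bins,
        )
    return survivors, n_kept
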