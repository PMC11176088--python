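"""Aggregate extracted submatrices: reductions, regularization, pileups.

The three all-in-one pileups cover the common genome-wide summaries:

- :func:`pileup_pixels` — aggregate peak analysis (APA): mean of the
  windows around a list of loop pixels, one matrix per file.
- :func:`pileup_domains` — aggregate TADs: each domain plus flanks is
  extracted as an on-diagonal block, optionally depth-normalized,
  resampled to a common side, and averaged.
- :func:`pileup_boundaries` — mean of fixed-width on-diagonal windows
  centered on boundary positions.

All means are missing-aware: NaN cells (balanced values at filtered bins)
never contribute, and a per-cell contributor count is tracked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .contact_io import ContactStore
from .extraction import (
    ExtractionConfig,
    JaggedSubmatrixArray,
    SubmatrixArray,
    pull_submatrices,
)
from .genome import GenomicRange
from .pairs import (
    ANCHOR_COLS,
    BinnedPairSet,
    PairSet,
    expand_pixels,
    remove_short_pairs,
    snap_to_bins,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AggregateMatrix",
    "RegularizeSpec",
    "agg_matrices",
    "regularize",
    "pileup_pixels",
    "pileup_domains",
    "pileup_boundaries",
]

AGG_FNS = ("sum", "mean", "median")


@dataclass
class AggregateMatrix:
    """A reduced matrix with per-cell contributor counts and provenance."""

    values: np.ndarray
    n_contributing: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.10g")

    def plot(self, path, cmap: str = "Reds"):
        """Write a diagnostic heatmap image (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(self.values, cmap=cmap)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


@dataclass
class RegularizeSpec:
    """Target geometry for resampling jagged submatrices."""

    ndim: int = 100
    scale_to_sum: bool = False

    def __post_init__(self):
        if self.ndim < 2:
            raise ValueError("ndim must be >= 2")


def _reduce(stack: np.ndarray, fn: str) -> Tuple[np.ndarray, np.ndarray]:
    """Missing-aware reduction over axis 0 of a (k, r, c) stack."""
    stack = np.asarray(stack, dtype=float)
    n_contrib = np.sum(~np.isnan(stack), axis=0)
    if fn == "sum":
        vals = np.nansum(stack, axis=0)
    elif fn == "mean":
        vals = np.nansum(stack, axis=0) / np.maximum(n_contrib, 1)
    elif fn == "median":
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmedian(stack, axis=0)
    else:
        raise ValueError(f"unknown aggregation fn {fn!r}; choose from {AGG_FNS}")
    vals = np.where(n_contrib > 0, vals, np.nan)
    return vals, n_contrib


def agg_matrices(
    arr: SubmatrixArray, by: str = "both", fn: str = "mean"
) -> Union[AggregateMatrix, List[AggregateMatrix]]:
    """Reduce a regular submatrix stack across interactions, files, or both.

    ``by="interactions"`` returns one matrix per file (reduced over
    interactions); ``by="files"`` one per interaction (reduced over
    files); ``by="both"`` a single matrix. Jagged input must be
    regularized first.
    """
    if isinstance(arr, JaggedSubmatrixArray):
        raise TypeError("jagged input: call regularize() before aggregating")
    counts = np.asarray(arr.counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty submatrix array")
    n, nf = counts.shape[:2]
    prov = {"fn": fn, "by": by, **arr.metadata}
    if by == "both":
        vals, nc = _reduce(counts.reshape(n * nf, *counts.shape[2:]), fn)
        return AggregateMatrix(vals, nc, prov)
    if by == "interactions":
        return [
            AggregateMatrix(*_reduce(counts[:, j], fn), {**prov, "file": arr.file_labels[j]})
            for j in range(nf)
        ]
    if by == "files":
        return [AggregateMatrix(*_reduce(counts[i], fn), prov) for i in range(n)]
    raise ValueError(f"unknown axis {by!r}; choose interactions, files, or both")


# ------------------------------------------------------------- regularize


def _bilinear_resample(mat: np.ndarray, ndim: int) -> np.ndarray:
    """Resample to ndim x ndim by bilinear interpolation on the unit square.

    Source and target cell centers are mapped to (i + 0.5)/n in [0, 1];
    target coordinates outside the source center range are clamped, so a
    matrix at its native size passes through unchanged.
    """
    mat = np.asarray(mat, dtype=float)
    r, c = mat.shape
    if (r, c) == (ndim, ndim):
        return mat.copy()
    src_r = (np.arange(r) + 0.5) / r
    src_c = (np.arange(c) + 0.5) / c
    tgt = (np.arange(ndim) + 0.5) / ndim
    interp = RegularGridInterpolator((src_r, src_c), mat, method="linear")
    rr = np.clip(tgt, src_r[0], src_r[-1])
    cc = np.clip(tgt, src_c[0], src_c[-1])
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    return interp(grid)


def regularize(
    arr: Union[JaggedSubmatrixArray, SubmatrixArray],
    spec: Union[RegularizeSpec, int] = 100,
    scale_to_sum: Optional[bool] = None,
) -> SubmatrixArray:
    """Resample per-interaction matrices to a common ndim x ndim shape.

    Matrices with either side < 2 cannot be interpolated and are dropped
    with a logged count. With ``scale_to_sum`` each output is rescaled so
    its total equals the source total.
    """
    if isinstance(spec, int):
        spec = RegularizeSpec(ndim=spec)
    if scale_to_sum is not None:
        spec = RegularizeSpec(spec.ndim, scale_to_sum)

    n = len(arr)
    nf = arr.n_files
    if isinstance(arr, JaggedSubmatrixArray):
        dims = arr.dims
    else:
        dims = np.tile(np.asarray(arr.counts.shape[2:]), (n, 1))
    keep = np.flatnonzero((dims[:, 0] >= 2) & (dims[:, 1] >= 2))
    if len(keep) < n:
        logger.info("regularize: dropped %d matrices with a side < 2", n - len(keep))
    if len(keep) == 0:
        raise ValueError("no matrices left to regularize")

    out = np.empty((len(keep), nf, spec.ndim, spec.ndim), dtype=float)
    for oi, i in enumerate(keep):
        for j in range(nf):
            src = np.asarray(arr.matrix(i, j), dtype=float)
            res = _bilinear_resample(src, spec.ndim)
            if spec.scale_to_sum:
                src_sum = src.sum()
                res_sum = res.sum()
                if res_sum != 0:
                    res = res * (src_sum / res_sum)
            out[oi, j] = res
    meta = {**arr.metadata, "regularized_to": spec.ndim, "scale_to_sum": spec.scale_to_sum}
    return SubmatrixArray(out, arr.interactions.take(keep), arr.file_labels, meta)


# ---------------------------------------------------------------- pileups


def pileup_pixels(
    files: Sequence[ContactStore],
    pairs: PairSet,
    binsize: int,
    buffer_bins: int = 5,
    normalization: str = "raw",
    drop_short: bool = True,
    anchor_point: str = "center",
    config: Optional[ExtractionConfig] = None,
) -> List[AggregateMatrix]:
    """Aggregate peak analysis: mean window around loop pixels, per file.

    Pipeline: snap to bins -> expand by ``buffer_bins`` -> drop windows
    leaving the chromosome -> optionally drop windows touching the
    diagonal band -> extract -> missing-aware mean over interactions.
    The mean (not the sum) keeps values comparable across list sizes.
    """
    config = config or ExtractionConfig(normalization=normalization)
    binned = snap_to_bins(pairs, binsize, anchor_point=anchor_point)
    expanded = expand_pixels(binned, buffer_bins)
    expanded, n_oob = expanded.drop_invalid()
    if drop_short:
        expanded, n_kept = remove_short_pairs(expanded, padding_bins=buffer_bins)
        logger.info("pileup_pixels: %d windows kept clear of the diagonal", n_kept)
    if len(expanded) == 0:
        raise ValueError("no pairs survive window expansion/diagonal filtering")
    arr = pull_submatrices(files, expanded, config)
    return agg_matrices(arr, by="interactions", fn="mean")


def _domain_windows(
    domains: Sequence[GenomicRange],
    binsize: int,
    buffer_frac: float,
    chromsizes,
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray, int]:
    """Expand domains by a fraction of their width; snap outward to bins."""
    rows = []
    lo_bins, hi_bins = [], []
    n_dropped = 0
    offs = chromsizes.offsets(binsize)
    for d in domains:
        w = len(d)
        s = d.start - buffer_frac * w
        e = d.end + buffer_frac * w
        if s < 0 or e > chromsizes[d.chrom]:
            n_dropped += 1
            continue
        lo = int(np.floor(s / binsize))
        hi = int(np.ceil(e / binsize))
        rows.append((d.chrom, lo * binsize, min(hi * binsize, chromsizes[d.chrom])))
        lo_bins.append(offs[d.chrom] + lo)
        hi_bins.append(offs[d.chrom] + hi)
    if n_dropped:
        logger.info("pileup_domains: dropped %d domains whose window leaves the chromosome", n_dropped)
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1"])
    if len(df):
        df["chrom2"], df["start2"], df["end2"] = df["chrom1"], df["start1"], df["end1"]
        df = df[ANCHOR_COLS]
    else:
        df = pd.DataFrame(columns=ANCHOR_COLS)
    return df, np.asarray(lo_bins, dtype=np.int64), np.asarray(hi_bins, dtype=np.int64), n_dropped


def pileup_domains(
    files: Sequence[ContactStore],
    domains: Sequence[GenomicRange],
    binsize: int,
    buffer_frac: float = 0.5,
    ndim: int = 100,
    normalization: str = "raw",
    per_matrix_norm: str = "sum",
    config: Optional[ExtractionConfig] = None,
) -> List[AggregateMatrix]:
    """Aggregate TAD plot: resampled mean of on-diagonal domain blocks.

    Each domain [s, e) is widened to [s - f*(e-s), e + f*(e-s)), snapped
    outward to whole bins, and its square on-diagonal block is extracted
    (a jagged stack, since domain widths differ). With
    ``per_matrix_norm="sum"`` each block is divided by its total first, so
    every domain contributes equal weight regardless of sequencing depth;
    blocks are then resampled to ``ndim`` and averaged per file.
    """
    if buffer_frac < 0:
        raise ValueError("buffer_frac must be >= 0")
    if per_matrix_norm not in ("none", "sum"):
        raise ValueError(f"unknown per_matrix_norm {per_matrix_norm!r}")
    config = config or ExtractionConfig(normalization=normalization)
    genome = files[0].chromsizes
    df, lo, hi, _ = _domain_windows(domains, binsize, buffer_frac, genome)
    if len(df) == 0:
        raise ValueError("all domain windows fall outside their chromosome")
    binned = BinnedPairSet(df, genome, binsize, lo, hi, lo, hi)
    arr = pull_submatrices(files, binned, config)
    if isinstance(arr, SubmatrixArray):  # all domains happen to share a width
        native = arr
    else:
        native = None
    if per_matrix_norm == "sum":
        if native is not None:
            counts = np.asarray(native.counts, dtype=float)
            totals = np.nansum(counts, axis=(2, 3), keepdims=True)
            totals[totals == 0] = 1.0
            native = SubmatrixArray(counts / totals, arr.interactions, arr.file_labels, arr.metadata)
        else:
            flat = np.asarray(arr.flat, dtype=float).copy()
            for i in range(len(arr)):
                r, c = arr.dims[i]
                for j in range(arr.n_files):
                    start = arr.offsets[i] + j * r * c
                    seg = flat[start : start + r * c]
                    tot = np.nansum(seg)
                    if tot != 0:
                        flat[start : start + r * c] = seg / tot
            arr = JaggedSubmatrixArray(
                flat, arr.offsets, arr.dims, arr.interactions, arr.file_labels, arr.metadata
            )
    reg = regularize(native if native is not None else arr, RegularizeSpec(ndim))
    return agg_matrices(reg, by="interactions", fn="mean")


def pileup_boundaries(
    files: Sequence[ContactStore],
    boundaries: Sequence,
    binsize: int,
    flank_bp: int = 100_000,
    normalization: str = "raw",
    config: Optional[ExtractionConfig] = None,
) -> List[AggregateMatrix]:
    """Mean on-diagonal window centered on each boundary position, per file.

    Boundaries are ``(chrom, position)`` pairs or
    :class:`~hicpile.genome.GenomicRange` objects (their midpoint is
    used). The window is the boundary's bin plus ``flank_bp // binsize``
    bins on each side — an odd side with the boundary bin at the exact
    center. Windows leaving the chromosome are dropped with a log message.
    """
    if flank_bp < binsize:
        raise ValueError("flank_bp must be >= binsize")
    config = config or ExtractionConfig(normalization=normalization)
    genome = files[0].chromsizes
    offs = genome.offsets(binsize)
    flank_bins = flank_bp // binsize
    rows, lo_bins, hi_bins = [], [], []
    n_dropped = 0
    for b in boundaries:
        if isinstance(b, GenomicRange):
            chrom, pos = b.chrom, b.center
        else:
            chrom, pos = b
        k = int(pos) // binsize
        nb = genome.n_bins(binsize, chrom)
        lo, hi = k - flank_bins, k + flank_bins + 1
        if lo < 0 or hi > nb:
            n_dropped += 1
            continue
        rows.append((chrom, lo * binsize, min(hi * binsize, genome[chrom])))
        lo_bins.append(offs[chrom] + lo)
        hi_bins.append(offs[chrom] + hi)
    if n_dropped:
        logger.info("pileup_boundaries: dropped %d out-of-range windows", n_dropped)
    if not rows:
        raise ValueError("no boundary windows fit inside their chromosome")
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1"])
    df["chrom2"], df["start2"], df["end2"] = df["chrom1"], df["start1"], df["end1"]
    binned = BinnedPairSet(
        df[ANCHOR_COLS], genome, binsize,
        np.asarray(lo_bins), np.asarray(hi_bins), np.asarray(lo_bins), np.asarray(hi_bins),
    )
    arr = pull_submatrices(files, binned, config)
    return agg_matrices(arr, by="interactions", fn="mean")
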