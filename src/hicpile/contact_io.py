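"""Read and write contact matrices in the cooler HDF5 dialect.

A .cool file stores one binned contact matrix as four HDF5 groups:
``chroms`` (name, length), ``bins`` (chrom, start, end, and optional
balancing-weight columns), ``pixels`` (a sparse upper-triangle COO table of
``bin1_id <= bin2_id`` with positive raw counts, sorted by bin1 then bin2),
and ``indexes`` (``chrom_offset`` into bins, ``bin1_offset`` into pixels).
A .mcool file nests one such group per resolution under
``resolutions/<N>``. :class:`ContactStore` keeps the pixel table on disk
and serves dense rectangular blocks via the ``bin1_offset`` index, so a
query reads only the pixel rows it touches.

Balanced counts follow the cooler convention: ``balanced = raw * w_i * w_j``
with per-bin weights; a missing (NaN) weight makes every balanced value in
that bin's row/column missing, while raw queries are unaffected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .genome import ChromSizes
from .pairs import ANCHOR_COLS, PairSet

__all__ = [
    "ContactStore",
    "DenseBlock",
    "open_contacts",
    "fetch_block",
    "write_contacts",
    "write_mcool",
    "read_bedpe",
    "read_bed",
]

_FORMAT = "HDF5::Cooler"
_FORMAT_VERSION = 3

NORMALIZATIONS = ("raw", "balanced")


@dataclass
class DenseBlock:
    """A dense rectangular block of (symmetrized) contact counts.

    ``row_bins`` / ``col_bins`` are half-open genome-wide bin intervals;
    ``values`` has shape ``(len(rows), len(cols))``. Raw blocks are
    non-negative integers; balanced blocks are floats with NaN exactly
    where either bin's weight is missing.
    """

    row_bins: Tuple[int, int]
    col_bins: Tuple[int, int]
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self):
        expect = (self.row_bins[1] - self.row_bins[0], self.col_bins[1] - self.col_bins[0])
        if self.values.shape != expect:
            raise ValueError(f"block shape {self.values.shape} != intervals {expect}")


class ContactStore:
    """Handle to one resolution of a cooler-dialect contact file.

    Use :func:`open_contacts` to construct. The pixel table stays on disk;
    :meth:`fetch` reads only the slice of pixel rows a query needs.
    """

    def __init__(self, path, group: str, resolution_bp: int):
        self.path = os.fspath(path)
        self._grp_name = group
        self._h5 = h5py.File(self.path, "r")
        grp = self._h5[group] if group else self._h5["/"]
        for req in ("chroms", "bins", "pixels", "indexes"):
            if req not in grp:
                raise ValueError(f"{self.path}: malformed cooler container, missing {req!r}")
        self._grp = grp
        self.resolution_bp = int(resolution_bp)
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in grp["chroms/name"][:]]
        lengths = grp["chroms/length"][:]
        self.chromsizes = ChromSizes(zip(names, lengths))
        self.n_bins = grp["bins/start"].shape[0]
        if self.n_bins != self.chromsizes.n_bins(self.resolution_bp):
            raise ValueError(
                f"{self.path}: bin table ({self.n_bins} bins) inconsistent with "
                f"chromsizes at {self.resolution_bp} bp"
            )
        self._bin1_offset = grp["indexes/bin1_offset"][:]
        self._px_bin1 = grp["pixels/bin1_id"]
        self._px_bin2 = grp["pixels/bin2_id"]
        self._px_count = grp["pixels/count"]
        self._weight_cache: Dict[str, np.ndarray] = {}

    # ------------------------------------------------------------- weights
    @property
    def weight_columns(self) -> Tuple[str, ...]:
        skip = {"chrom", "start", "end"}
        return tuple(k for k in self._grp["bins"] if k not in skip)

    def weights(self, name: str = "weight") -> np.ndarray:
        """Per-bin balancing weights (NaN = bin filtered out by balancing)."""
        if name not in self._weight_cache:
            if name not in self._grp["bins"]:
                raise KeyError(
                    f"{self.path}: no weight column {name!r}; "
                    f"available: {list(self.weight_columns)}"
                )
            self._weight_cache[name] = self._grp["bins"][name][:].astype(float)
        return self._weight_cache[name]

    @property
    def bins(self) -> pd.DataFrame:
        grp = self._grp["bins"]
        chrom_ids = grp["chrom"][:]
        names = np.asarray(self.chromsizes.names, dtype=object)
        df = pd.DataFrame(
            {"chrom": names[chrom_ids], "start": grp["start"][:], "end": grp["end"][:]}
        )
        for col in self.weight_columns:
            df[col] = grp[col][:]
        return df

    @property
    def nnz(self) -> int:
        return self._px_bin1.shape[0]

    # --------------------------------------------------------------- fetch
    def _pixels_between(self, r1: Tuple[int, int], r2: Tuple[int, int]):
        """Stored triples with bin1 in r1 and bin2 in r2 (upper-tri storage)."""
        s, e = self._bin1_offset[r1[0]], self._bin1_offset[r1[1]]
        b1 = self._px_bin1[s:e]
        b2 = self._px_bin2[s:e]
        m = (b2 >= r2[0]) & (b2 < r2[1])
        return b1[m], b2[m], self._px_count[s:e][m]

    def fetch(
        self,
        region1: Tuple[int, int],
        region2: Tuple[int, int],
        normalization: str = "raw",
        weight_name: str = "weight",
    ) -> DenseBlock:
        """Dense block of symmetrized counts for two bin intervals.

        Triples are mirrored across the diagonal, so queries need not
        respect the upper-triangle storage and
        ``fetch(r1, r2) == fetch(r2, r1).T`` for every normalization.
        """
        if normalization not in NORMALIZATIONS:
            raise ValueError(
                f"unknown normalization {normalization!r}; choose from {NORMALIZATIONS}"
            )
        for lo, hi in (region1, region2):
            if not (0 <= lo < hi <= self.n_bins):
                raise ValueError(
                    f"bin interval [{lo}, {hi}) out of range (n_bins={self.n_bins})"
                )
        n1 = region1[1] - region1[0]
        n2 = region2[1] - region2[0]
        A = np.zeros((n1, n2), dtype=np.int64)
        b1, b2, c = self._pixels_between(region1, region2)
        np.add.at(A, (b1 - region1[0], b2 - region2[0]), c)
        b1, b2, c = self._pixels_between(region2, region1)
        offdiag = b1 != b2  # diagonal triples were already placed by the first pass
        np.add.at(
            A, (b2[offdiag] - region1[0], b1[offdiag] - region2[0]), c[offdiag]
        )
        if normalization == "raw":
            return DenseBlock(tuple(region1), tuple(region2), A, "raw")
        w = self.weights(weight_name)
        wr = w[region1[0] : region1[1]]
        wc = w[region2[0] : region2[1]]
        vals = A.astype(float) * wr[:, None] * wc[None, :]
        # a filtered bin (NaN weight) is missing even where no pixel is stored
        vals[np.isnan(wr), :] = np.nan
        vals[:, np.isnan(wc)] = np.nan
        return DenseBlock(tuple(region1), tuple(region2), vals, "balanced")

    def close(self) -> None:
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def __repr__(self) -> str:
        return (
            f"ContactStore({self.path!r}, resolution={self.resolution_bp}, "
            f"n_bins={self.n_bins}, nnz={self.nnz})"
        )


def open_contacts(path, resolution_bp: Optional[int] = None) -> ContactStore:
    """Open a .cool (single-resolution) or .mcool (multi-resolution) file.

    For .mcool containers ``resolution_bp`` selects the stored resolution;
    for single-resolution files it may be omitted (and is checked against
    the file when given).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as h5:
        if "resolutions" in h5:
            avail = sorted(int(k) for k in h5["resolutions"])
            if resolution_bp is None or int(resolution_bp) not in avail:
                raise ValueError(
                    f"{path}: resolution {resolution_bp} not present; available: {avail}"
                )
            return ContactStore(path, f"resolutions/{int(resolution_bp)}", int(resolution_bp))
        if "bins" not in h5 or "pixels" not in h5:
            raise ValueError(f"{path}: malformed cooler container (missing bins/pixels)")
        stored = int(h5.attrs.get("bin-size", 0)) or int(h5["bins/end"][0] - h5["bins/start"][0])
        if resolution_bp is not None and int(resolution_bp) != stored:
            raise ValueError(
                f"{path}: resolution {resolution_bp} not present; available: [{stored}]"
            )
        return ContactStore(path, "", stored)


def fetch_block(
    store: ContactStore,
    region1: Tuple[int, int],
    region2: Tuple[int, int],
    normalization: str = "raw",
    weight_name: str = "weight",
) -> DenseBlock:
    """Functional alias for :meth:`ContactStore.fetch`."""
    return store.fetch(region1, region2, normalization, weight_name)


# ---------------------------------------------------------------- writing

def _write_cooler_group(
    grp: h5py.Group,
    dense_by_chrom: Mapping[str, np.ndarray],
    chromsizes: ChromSizes,
    resolution_bp: int,
    weights: Optional[np.ndarray],
    weight_name: str = "weight",
) -> None:
    n_bins = chromsizes.n_bins(resolution_bp)
    # validate and collect upper-triangle triples per chromosome
    tri_b1, tri_b2, tri_c = [], [], []
    offsets = chromsizes.offsets(resolution_bp)
    for chrom, length in chromsizes:
        if chrom not in dense_by_chrom:
            continue
        M = np.asarray(dense_by_chrom[chrom])
        side = chromsizes.n_bins(resolution_bp, chrom)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"{chrom}: matrix must be square, got {M.shape}")
        if M.shape[0] != side:
            raise ValueError(
                f"{chrom}: matrix side {M.shape[0]} != ceil({length}/{resolution_bp}) = {side}"
            )
        if np.any(M < 0):
            raise ValueError(f"{chrom}: negative counts")
        if not np.array_equal(M, M.T):
            raise ValueError(f"{chrom}: matrix is not symmetric")
        i, j = np.nonzero(np.triu(M))
        tri_b1.append(i + offsets[chrom])
        tri_b2.append(j + offsets[chrom])
        tri_c.append(M[i, j])
    unknown = set(dense_by_chrom) - set(chromsizes.names)
    if unknown:
        raise ValueError(f"matrices for unknown chromosomes: {sorted(unknown)}")
    if tri_b1:
        b1 = np.concatenate(tri_b1).astype(np.int64)
        b2 = np.concatenate(tri_b2).astype(np.int64)
        c = np.concatenate(tri_c).astype(np.int64)
        order = np.lexsort((b2, b1))
        b1, b2, c = b1[order], b2[order], c[order]
    else:
        b1 = b2 = c = np.empty(0, dtype=np.int64)

    opts = dict(track_times=False)
    chroms = grp.create_group("chroms")
    chroms.create_dataset(
        "name", data=np.array(chromsizes.names, dtype="S"), **opts
    )
    chroms.create_dataset("length", data=np.asarray(chromsizes.lengths, np.int64), **opts)

    bin_chrom = np.empty(n_bins, dtype=np.int32)
    bin_start = np.empty(n_bins, dtype=np.int64)
    bin_end = np.empty(n_bins, dtype=np.int64)
    for ci, (chrom, length) in enumerate(chromsizes):
        lo, hi = chromsizes.bin_span(chrom, resolution_bp)
        starts = np.arange(hi - lo, dtype=np.int64) * resolution_bp
        bin_chrom[lo:hi] = ci
        bin_start[lo:hi] = starts
        bin_end[lo:hi] = np.minimum(starts + resolution_bp, length)
    bins = grp.create_group("bins")
    bins.create_dataset("chrom", data=bin_chrom, **opts)
    bins.create_dataset("start", data=bin_start, **opts)
    bins.create_dataset("end", data=bin_end, **opts)
    if weights is not None:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (n_bins,):
            raise ValueError(f"weights length {weights.shape} != n_bins {n_bins}")
        bins.create_dataset(weight_name, data=weights, **opts)

    pixels = grp.create_group("pixels")
    pixels.create_dataset("bin1_id", data=b1, **opts)
    pixels.create_dataset("bin2_id", data=b2, **opts)
    pixels.create_dataset("count", data=c, **opts)

    indexes = grp.create_group("indexes")
    chrom_offset = np.concatenate(
        [[0], np.cumsum([chromsizes.n_bins(resolution_bp, n) for n in chromsizes.names])]
    )
    indexes.create_dataset("chrom_offset", data=chrom_offset.astype(np.int64), **opts)
    bin1_offset = np.searchsorted(b1, np.arange(n_bins + 1))
    indexes.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64), **opts)

    grp.attrs["format"] = _FORMAT
    grp.attrs["format-version"] = _FORMAT_VERSION
    grp.attrs["bin-size"] = int(resolution_bp)
    grp.attrs["bin-type"] = "fixed"
    grp.attrs["nbins"] = int(n_bins)
    grp.attrs["nchroms"] = len(chromsizes)
    grp.attrs["nnz"] = int(len(c))
    grp.attrs["storage-mode"] = "symmetric-upper"


def write_contacts(
    dense_by_chrom: Mapping[str, np.ndarray],
    chromsizes: ChromSizes,
    resolution_bp: int,
    weights: Optional[np.ndarray],
    path,
) -> ContactStore:
    """Write per-chromosome symmetric count matrices as a .cool file.

    Only intra-chromosomal upper-triangle nonzeros are stored. Returns an
    opened :class:`ContactStore` on the new file.
    """
    with h5py.File(path, "w") as h5:
        _write_cooler_group(h5["/"], dense_by_chrom, chromsizes, resolution_bp, weights)
    return open_contacts(path, resolution_bp)


def write_mcool(
    per_resolution: Mapping[int, Mapping[str, np.ndarray]],
    chromsizes: ChromSizes,
    path,
    weights: Optional[Mapping[int, np.ndarray]] = None,
) -> None:
    """Write a multi-resolution .mcool container (one group per bin size)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "HDF5::MCOOL"
        h5.attrs["format-version"] = 2
        res_grp = h5.create_group("resolutions")
        for res, dense in sorted(per_resolution.items()):
            w = weights.get(res) if weights else None
            _write_cooler_group(res_grp.create_group(str(int(res))), dense, chromsizes, int(res), w)


# ---------------------------------------------------------------- BEDPE/BED

_BEDPE_DEFAULT_NAMES = ["name", "score", "strand1", "strand2"]


def read_bedpe(path, genome: ChromSizes) -> PairSet:
    """Read paired intervals from a BEDPE text file.

    Tab-separated, >= 6 columns, 0-based half-open. An optional single
    header line starting with ``#`` names the columns; otherwise extra
    columns get conventional names (name, score, strand1, strand2, col11,
    ...). Chromosomes are validated against ``genome`` and
    intra-chromosomal pairs are canonically oriented so that
    ``anchor1.start <= anchor2.start``.
    """
    header = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        header = first.lstrip("#").strip().split("\t")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        return PairSet(pd.DataFrame(columns=ANCHOR_COLS), genome)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs >= 6 columns, found {df.shape[1]}")
    names = list(ANCHOR_COLS)
    n_extra = df.shape[1] - 6
    if header is not None and len(header) == df.shape[1]:
        names = header
        names[:6] = ANCHOR_COLS  # anchor columns are positional regardless of header text
    else:
        for k in range(n_extra):
            names.append(
                _BEDPE_DEFAULT_NAMES[k] if k < len(_BEDPE_DEFAULT_NAMES) else f"col{k + 7}"
            )
    df.columns = names
    for col in ("start1", "end1", "start2", "end2"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    for col in df.columns[6:]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass

    # line numbers for error messages: data lines only, 1-based incl. header
    first_data_line = 2 if header is not None else 1
    for i in range(len(df)):
        lineno = first_data_line + i
        for side in ("1", "2"):
            chrom = df.iloc[i][f"chrom{side}"]
            if chrom not in genome:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            s, e = int(df.iloc[i][f"start{side}"]), int(df.iloc[i][f"end{side}"])
            if e <= s or s < 0:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{s}, {e})")
            if e > genome[chrom]:
                raise ValueError(
                    f"{path}: line {lineno}: interval end {e} beyond {chrom!r} "
                    f"(length {genome[chrom]})"
                )

    intra = (df["chrom1"] == df["chrom2"]).to_numpy()
    flip = intra & (df["start1"].to_numpy() > df["start2"].to_numpy())
    if flip.any():
        for col in ("chrom", "start", "end"):
            a, b = df[f"{col}1"].to_numpy().copy(), df[f"{col}2"].to_numpy().copy()
            df[f"{col}1"] = np.where(flip, b, a)
            df[f"{col}2"] = np.where(flip, a, b)
    return PairSet(df, genome)


def read_bed(path, genome: ChromSizes):
    """Read BED3+ intervals as a list of :class:`~hicpile.genome.GenomicRange`."""
    from .genome import GenomicRange

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom not in genome:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            if end <= start or end > genome[chrom]:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            out.append(GenomicRange(chrom, start, end))
    return out
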