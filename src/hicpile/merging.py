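"""Merge redundant loop calls across replicates, callers, or conditions.

Loop callers run on replicate Hi-C maps assign the same underlying loop to
slightly different pixels. Calls are pooled, snapped to a common bin grid,
and clustered per chromosome pair with DBSCAN (min_samples=2, Manhattan
distance on bin coordinates scaled to base pairs, eps = ``radius_bp``).
With min_samples=2 every point within eps of another is itself core, so
clusters are exactly the connected components of the <=eps distance graph;
DBSCAN noise points (isolated calls) are kept as singleton clusters rather
than discarded. One representative pixel is chosen per cluster and all
original calls and their metadata are retained with full provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .pairs import ANCHOR_COLS, BinnedPairSet, PairSet, snap_to_bins

__all__ = ["MergedPairSet", "merge_pairs"]

SELECTIONS = ("max_metric", "mean_position", "most_frequent")


@dataclass
class MergedPairSet:
    """Merged loop calls with full provenance.

    ``representatives`` holds one pixel per cluster (in cluster-id order);
    ``membership`` maps each cluster id to the indices of its member calls
    in ``originals``, the concatenated input with source labels; and
    ``selection_record`` stores the selection rule and the winning value
    per cluster (metric value, modal-pixel frequency, or distance to the
    cluster mean).
    """

    representatives: BinnedPairSet
    membership: Dict[int, List[int]]
    originals: BinnedPairSet
    cluster_ids: np.ndarray  # per original call
    selection_record: Dict

    @property
    def n_clusters(self) -> int:
        return len(self.membership)

    def cluster_members(self, cluster_id: int) -> BinnedPairSet:
        return self.originals.take(self.membership[cluster_id])

    def to_bedpe(self, path) -> None:
        """Write representatives as BEDPE with provenance columns."""
        self.representatives.to_bedpe(path)


def _cluster_chrom_pair(coords_bp: np.ndarray, radius_bp: float) -> np.ndarray:
    """Connected-component labels for pixels at Manhattan distance <= radius."""
    n = len(coords_bp)
    if n == 1:
        return np.zeros(1, dtype=int)
    if radius_bp == 0:
        # sklearn requires eps > 0; at radius 0 only identical pixels merge
        _, labels = np.unique(coords_bp, axis=0, return_inverse=True)
        return labels
    labels = DBSCAN(eps=radius_bp, min_samples=2, metric="cityblock").fit_predict(coords_bp)
    # noise (-1) -> singleton clusters
    next_id = labels.max() + 1 if (labels >= 0).any() else 0
    out = labels.copy()
    for i in np.flatnonzero(labels == -1):
        out[i] = next_id
        next_id += 1
    return out


def _pick_representative(
    members: np.ndarray,
    b1: np.ndarray,
    b2: np.ndarray,
    metric: Optional[np.ndarray],
    selection: str,
):
    """Return (original index of the representative, winning value)."""
    if selection == "max_metric":
        vals = metric[members]
        best = members[int(np.argmax(vals))]  # argmax keeps first on ties
        return best, float(metric[best])
    if selection == "most_frequent":
        coords = np.stack([b1[members], b2[members]], axis=1)
        uniq, inverse, counts = np.unique(
            coords, axis=0, return_inverse=True, return_counts=True
        )
        best_count = counts.max()
        modal = np.flatnonzero(counts[inverse] == best_count)  # members at a modal pixel
        cands = members[modal]
        if len(cands) > 1 and metric is not None:
            best = cands[int(np.argmax(metric[cands]))]
        else:
            best = cands[0]
        return best, int(best_count)
    if selection == "mean_position":
        mean1 = b1[members].mean()
        mean2 = b2[members].mean()
        d = np.abs(b1[members] - mean1) + np.abs(b2[members] - mean2)
        best = members[int(np.argmin(d))]
        return best, float(d.min())
    raise ValueError(f"unknown selection {selection!r}; choose from {SELECTIONS}")


def merge_pairs(
    pair_lists: Sequence[PairSet],
    binsize_bp: int,
    radius_bp: float,
    metric_column: Optional[str] = None,
    selection: Optional[str] = None,
    labels: Optional[Sequence[str]] = None,
    chromsizes=None,
) -> MergedPairSet:
    """Cluster pooled loop calls and pick one representative per cluster.

    Parameters
    ----------
    pair_lists:
        Loop-call lists (e.g. one per replicate or caller). Each list's
        ``source`` labels, or ``labels``, tag the provenance of every call.
    binsize_bp:
        Bin grid the calls are snapped to before clustering.
    radius_bp:
        DBSCAN eps: two calls are linked when their Manhattan distance on
        the bp-scaled bin grid is at most this. 0 merges exact duplicates
        only.
    metric_column:
        Metadata column (e.g. a count or a loop-strength score) used by
        ``max_metric`` selection and as the tie-break for ``most_frequent``.
    selection:
        ``max_metric`` | ``most_frequent`` | ``mean_position``. Defaults to
        ``max_metric`` when a metric column is given, else ``most_frequent``.
    """
    if radius_bp < 0:
        raise ValueError("radius_bp must be non-negative")
    if selection is None:
        selection = "max_metric" if metric_column is not None else "most_frequent"
    if selection not in SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}; choose from {SELECTIONS}")
    if selection == "max_metric" and metric_column is None:
        raise ValueError("selection='max_metric' requires metric_column")
    if metric_column is not None:
        for k, ps in enumerate(pair_lists):
            if metric_column not in ps.df.columns:
                raise ValueError(f"pair list {k} lacks metric column {metric_column!r}")

    pooled = PairSet.concat(pair_lists, labels=labels)
    binned = snap_to_bins(pooled, binsize_bp, chromsizes=chromsizes)
    b1, b2 = binned.bin1, binned.bin2
    metric = (
        binned.df[metric_column].to_numpy(dtype=float) if metric_column is not None else None
    )

    cluster_ids = np.full(len(binned), -1, dtype=int)
    next_global = 0
    key = binned.df["chrom1"].astype(str) + "|" + binned.df["chrom2"].astype(str)
    # chromosome-pair namespaces, visited in first-appearance order
    for cp in pd.unique(key):
        idx = np.flatnonzero((key == cp).to_numpy())
        coords_bp = np.stack([b1[idx], b2[idx]], axis=1).astype(float) * binsize_bp
        local = _cluster_chrom_pair(coords_bp, float(radius_bp))
        # renumber local labels by first appearance so ids are order-stable
        remap: Dict[int, int] = {}
        for i, lab in zip(idx, local):
            if lab not in remap:
                remap[lab] = next_global
                next_global += 1
            cluster_ids[i] = remap[lab]

    membership: Dict[int, List[int]] = {}
    for i, cid in enumerate(cluster_ids):
        membership.setdefault(int(cid), []).append(i)

    rep_idx, winning = [], []
    for cid in sorted(membership):
        members = np.asarray(membership[cid], dtype=int)
        best, value = _pick_representative(members, b1, b2, metric, selection)
        rep_idx.append(int(best))
        winning.append(value)

    reps = binned.take(np.asarray(rep_idx))
    rep_df = reps.df.copy()
    rep_df["cluster_id"] = sorted(membership)
    rep_df["cluster_size"] = [len(membership[cid]) for cid in sorted(membership)]
    rep_df["selection_value"] = winning
    representatives = BinnedPairSet(
        rep_df, reps.chromsizes, reps.binsize,
        reps.row_start, reps.row_stop, reps.col_start, reps.col_stop,
        reps.valid, reps.source,
    )
    record = {
        "selection": selection,
        "metric_column": metric_column,
        "radius_bp": float(radius_bp),
        "winning_values": dict(zip(sorted(membership), winning)),
    }
    return MergedPairSet(representatives, membership, binned, cluster_ids, record)
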