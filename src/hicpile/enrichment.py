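"""Loop-strength scoring: pixel enrichment over a customizable local background.

A pixel's "loop strength" is the enrichment of a foreground selection
(by default the focal pixel) over a background selection (by default a
donut ring clear of the peak and of its row/column stripes) inside the
surrounding submatrix. The default score is a pseudocounted median ratio,

    score = (median(foreground) + 1) / (median(background) + 1),

which is 1 on a flat field, robust to outliers in the ring, and defined on
sparse windows thanks to the pseudocount. Missing (NaN) cells are excluded
from both medians; if the background has no non-missing cell the score is
missing, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .contact_io import ContactStore
from .extraction import ExtractionConfig, pull_submatrices
from .pairs import BinnedPairSet, expand_pixels

__all__ = ["SelectionMask", "make_mask", "calc_loop_enrichment", "EnrichmentResult"]

MASK_KINDS = (
    "focal", "donut", "inner_square", "outer_ring", "top_left", "bottom_right", "rows_cols",
)


@dataclass(frozen=True)
class SelectionMask:
    """A named boolean selection over an n x n window (n odd)."""

    cells: np.ndarray
    name: str

    def __post_init__(self):
        cells = np.asarray(self.cells, dtype=bool)
        object.__setattr__(self, "cells", cells)
        if cells.ndim != 2 or cells.shape[0] != cells.shape[1]:
            raise ValueError("mask must be square")
        if cells.shape[0] % 2 == 0:
            raise ValueError("mask side must be odd")
        # empty masks are legal intermediates of the algebra; scoring rejects them

    @property
    def side(self) -> int:
        return self.cells.shape[0]

    @property
    def n_selected(self) -> int:
        return int(self.cells.sum())

    def _check(self, other: "SelectionMask") -> None:
        if other.side != self.side:
            raise ValueError("masks have different sides")

    def union(self, other: "SelectionMask") -> "SelectionMask":
        self._check(other)
        return SelectionMask(self.cells | other.cells, f"({self.name})|({other.name})")

    def intersection(self, other: "SelectionMask") -> "SelectionMask":
        self._check(other)
        return SelectionMask(self.cells & other.cells, f"({self.name})&({other.name})")

    def difference(self, other: "SelectionMask") -> "SelectionMask":
        self._check(other)
        return SelectionMask(self.cells & ~other.cells, f"({self.name})-({other.name})")

    def complement(self) -> "SelectionMask":
        return SelectionMask(~self.cells, f"!({self.name})")

    def overlaps(self, other: "SelectionMask") -> bool:
        self._check(other)
        return bool((self.cells & other.cells).any())


def make_mask(kind: str, side: int, **params) -> SelectionMask:
    """Build one of the standard selection geometries on an odd-sided window.

    kinds
    -----
    - ``focal``: the center cell only.
    - ``donut(inner, outer)``: cells at Chebyshev distance d from the
      center with ``inner <= d <= outer``, excluding the center's row and
      column (stripe artifacts); pass ``include_axes=True`` to keep them.
    - ``inner_square(k)``: the centered (2k+1)^2 block.
    - ``outer_ring(k)``: all cells at Chebyshev distance > k from center.
    - ``top_left(k)`` / ``bottom_right(k)``: k x k corner blocks.
    - ``rows_cols``: center row and center column, minus the center.
    """
    if side < 1 or side % 2 == 0:
        raise ValueError("side must be an odd integer >= 1")
    if kind not in MASK_KINDS:
        raise ValueError(f"unknown mask kind {kind!r}; choose from {MASK_KINDS}")
    c = side // 2
    ii, jj = np.indices((side, side))
    cheb = np.maximum(np.abs(ii - c), np.abs(jj - c))
    cells = np.zeros((side, side), dtype=bool)

    if kind == "focal":
        cells[c, c] = True
    elif kind == "donut":
        inner = int(params.get("inner", 1))
        outer = int(params.get("outer", c))
        if not (1 <= inner < outer <= c):
            raise ValueError(f"donut needs 1 <= inner < outer <= {c}, got ({inner}, {outer})")
        cells = (cheb >= inner) & (cheb <= outer)
        if not params.get("include_axes", False):
            cells[c, :] = False
            cells[:, c] = False
    elif kind == "inner_square":
        k = int(params.get("k", 1))
        if not 0 <= k <= c:
            raise ValueError(f"inner_square needs 0 <= k <= {c}")
        cells = cheb <= k
    elif kind == "outer_ring":
        k = int(params.get("k", c - 1))
        if not 0 <= k < c:
            raise ValueError(f"outer_ring needs 0 <= k < {c}")
        cells = cheb > k
    elif kind in ("top_left", "bottom_right"):
        k = int(params.get("k", 1))
        if not 1 <= k <= side:
            raise ValueError(f"corner block needs 1 <= k <= {side}")
        if kind == "top_left":
            cells[:k, :k] = True
        else:
            cells[-k:, -k:] = True
    elif kind == "rows_cols":
        cells[c, :] = True
        cells[:, c] = True
        cells[c, c] = False
    name = kind if not params else f"{kind}({', '.join(f'{k}={v}' for k, v in params.items())})"
    return SelectionMask(cells, name)


@dataclass
class EnrichmentResult:
    """Per-(interaction, file) enrichment scores with the masks used."""

    scores: np.ndarray  # (n_interactions, n_files)
    interactions: BinnedPairSet
    file_labels: list
    fg_mask: SelectionMask
    bg_mask: SelectionMask
    score_definition: str

    def to_frame(self):
        import pandas as pd
        from .pairs import ANCHOR_COLS

        df = self.interactions.df[ANCHOR_COLS].copy()
        for j, lab in enumerate(self.file_labels):
            df[f"enrichment_{lab}"] = self.scores[:, j]
        return df

    def to_bedpe(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=True)


def median_ratio(fg: np.ndarray, bg: np.ndarray) -> float:
    """Default score: (median(fg) + 1) / (median(bg) + 1), NaNs excluded."""
    fg = fg[~np.isnan(fg)]
    bg = bg[~np.isnan(bg)]
    if len(fg) == 0 or len(bg) == 0:
        return np.nan
    return (np.median(fg) + 1.0) / (np.median(bg) + 1.0)


def score_window(window: np.ndarray, fg: SelectionMask, bg: SelectionMask,
                 score: Callable[[np.ndarray, np.ndarray], float] = median_ratio) -> float:
    """Score a single (2*buffer+1)^2 window with the given masks."""
    window = np.asarray(window, dtype=float)
    return score(window[fg.cells], window[bg.cells])


def calc_loop_enrichment(
    files: Sequence[ContactStore],
    pairs: BinnedPairSet,
    buffer_bins: int = 5,
    fg: Optional[SelectionMask] = None,
    bg: Optional[SelectionMask] = None,
    score: Union[str, Callable] = "median_ratio",
    config: Optional[ExtractionConfig] = None,
) -> EnrichmentResult:
    """Score each pixel's enrichment over its local background, per file.

    Each single-pixel pair is expanded to a (2*buffer+1)-bin window (pairs
    whose window leaves the chromosome are dropped with a log message);
    the window is extracted from every file and scored with
    ``score(fg_values, bg_values)``. Pairs whose window overlaps the
    diagonal band are scored anyway but trigger a warning — filter with
    :func:`~hicpile.pairs.remove_short_pairs` (padding >= buffer) to avoid
    diagonal contamination.
    """
    side = 2 * buffer_bins + 1
    if fg is None:
        fg = make_mask("focal", side)
    if bg is None:
        if buffer_bins >= 2:
            bg = make_mask("donut", side, inner=min(2, buffer_bins - 1), outer=buffer_bins)
        elif buffer_bins == 1:
            bg = make_mask("outer_ring", side, k=0)
        else:
            raise ValueError("buffer_bins must be >= 1 to form a background")
    if fg.side != side or bg.side != side:
        raise ValueError(f"mask side must be 2*buffer+1 = {side}")
    if fg.n_selected == 0 or bg.n_selected == 0:
        raise ValueError("foreground and background masks must each select a cell")
    if fg.overlaps(bg):
        raise ValueError("foreground and background masks overlap")
    if callable(score):
        score_fn, definition = score, getattr(score, "__name__", "user_function")
    elif score == "median_ratio":
        score_fn, definition = median_ratio, "(median(fg) + 1) / (median(bg) + 1)"
    else:
        raise ValueError(f"unknown score {score!r}")

    expanded = expand_pixels(pairs, buffer_bins)
    expanded, n_dropped = expanded.drop_invalid()
    if len(expanded) == 0:
        raise ValueError("no pairs remain after dropping out-of-range windows")
    gap = expanded.col_start - (expanded.row_stop - 1)
    touching = expanded.is_intra() & (gap < 0)
    if touching.any():
        warnings.warn(
            f"{int(touching.sum())} windows overlap the diagonal; scores include "
            "diagonal counts (pre-filter with remove_short_pairs to avoid this)",
            stacklevel=2,
        )

    arr = pull_submatrices(files, expanded, config)
    scores = np.empty((len(expanded), len(files)), dtype=float)
    for i in range(len(expanded)):
        for j in range(len(files)):
            scores[i, j] = score_fn(
                np.asarray(arr.matrix(i, j), dtype=float)[fg.cells],
                np.asarray(arr.matrix(i, j), dtype=float)[bg.cells],
            )
    return EnrichmentResult(scores, expanded, arr.file_labels, fg, bg, definition)
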