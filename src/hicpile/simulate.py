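"""Deterministic synthetic Hi-C data with known ground truth.

The simulator produces intra-chromosomal contact maps from a noiseless
intensity matrix

    Lambda_ij = depth * (|i - j| + 1)^(-alpha) * L_ij * T_ij * b_i * b_j

where the power-law term is the distance decay, ``L`` multiplies a
Gaussian bump (in Chebyshev radius, peak ``fold``) at each planted loop,
``T`` multiplies ``fold`` inside each planted TAD block, and ``b`` is a
multiplicative per-bin bias. Observed counts are Poisson(Lambda),
symmetrized; the stored balancing weights are exactly ``1 / b``, so
balanced counts have bias-free expectation. Everything is a pure function
of (spec, seed).

Poisson noise (rather than negative binomial) keeps expectations and
standard errors closed-form; overdispersion is an extension hook.

:func:`simulate_loop_calls` emulates replicate loop-caller output: each
true loop appears in a replicate with probability ``1 - fnr``, displaced
by a uniform integer jitter — the "same loop, slightly different pixel"
situation that loop merging exists to resolve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contact_io import ContactStore, write_contacts
from .genome import ChromSizes
from .pairs import ANCHOR_COLS, PairSet

__all__ = [
    "Loop",
    "Tad",
    "MapSpec",
    "GroundTruth",
    "make_bias",
    "simulate_contact_map",
    "simulate_loop_calls",
]


@dataclass(frozen=True)
class Loop:
    """A planted focal enrichment at chromosome-local pixel (bin1, bin2)."""

    chrom: str
    bin1: int
    bin2: int
    fold: float = 5.0
    width_bins: float = 1.0

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError("loop fold must be >= 1")
        if self.bin1 > self.bin2:
            object.__setattr__(self, "bin1", self.bin2)
            object.__setattr__(self, "bin2", self.bin1)


@dataclass(frozen=True)
class Tad:
    """A planted on-diagonal block [start_bin, end_bin) of elevated contact."""

    chrom: str
    start_bin: int
    end_bin: int
    fold: float = 2.0

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError("tad fold must be >= 1")
        if self.end_bin <= self.start_bin:
            raise ValueError("tad needs end_bin > start_bin")


@dataclass
class MapSpec:
    """Full description of one simulated multi-chromosome contact map."""

    chromsizes: ChromSizes
    binsize_bp: int
    decay_exponent: float = 1.0
    depth: float = 100.0
    loops: Sequence[Loop] = field(default_factory=list)
    tads: Sequence[Tad] = field(default_factory=list)
    bias: Optional[np.ndarray] = None  # genome-wide per-bin positive reals
    seed: int = 0

    def __post_init__(self):
        if self.binsize_bp <= 0:
            raise ValueError("binsize_bp must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        n_bins = self.chromsizes.n_bins(self.binsize_bp)
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (n_bins,):
                raise ValueError(f"bias length {self.bias.shape} != n_bins {n_bins}")
            if not np.all(np.isfinite(self.bias)) or np.any(self.bias <= 0):
                raise ValueError("bias must be finite and positive")
        for lp in self.loops:
            nb = self.chromsizes.n_bins(self.binsize_bp, lp.chrom)
            if not (0 <= lp.bin1 <= lp.bin2 < nb):
                raise ValueError(f"loop {lp} outside {lp.chrom} ({nb} bins)")
        for td in self.tads:
            nb = self.chromsizes.n_bins(self.binsize_bp, td.chrom)
            if not (0 <= td.start_bin < td.end_bin <= nb):
                raise ValueError(f"tad {td} outside {td.chrom} ({nb} bins)")


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analysis must recover."""

    lam: Dict[str, np.ndarray]  # noiseless intensity per chromosome
    counts: Dict[str, np.ndarray]  # the sampled symmetric count matrices
    loops: List[Loop]
    tads: List[Tad]
    weights: np.ndarray  # stored balancing weights, = 1 / bias
    chromsizes: ChromSizes
    binsize_bp: int

    def loop_pixels_bp(self) -> PairSet:
        """True loop pixels as a PairSet in base-pair coordinates."""
        rows = []
        bs = self.binsize_bp
        for lp in self.loops:
            length = self.chromsizes[lp.chrom]
            rows.append(
                (
                    lp.chrom, lp.bin1 * bs, min((lp.bin1 + 1) * bs, length),
                    lp.chrom, lp.bin2 * bs, min((lp.bin2 + 1) * bs, length),
                    lp.fold,
                )
            )
        df = pd.DataFrame(rows, columns=ANCHOR_COLS + ["fold"])
        return PairSet(df, self.chromsizes)

    def to_json(self, path) -> None:
        """Write a plain-JSON sidecar (loops, tads, weights; not matrices)."""
        payload = {
            "binsize_bp": self.binsize_bp,
            "chromsizes": list(map(list, self.chromsizes)),
            "loops": [
                [l.chrom, l.bin1, l.bin2, l.fold, l.width_bins] for l in self.loops
            ],
            "tads": [[t.chrom, t.start_bin, t.end_bin, t.fold] for t in self.tads],
            "weights": self.weights.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def make_bias(n_bins: int, sd: float = 0.3, seed: int = 0) -> np.ndarray:
    """Log-normal per-bin bias with unit mean (sd on the log scale)."""
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(-sd * sd / 2.0, sd, size=n_bins))


def _loop_factor(n: int, loops: Sequence[Loop]) -> np.ndarray:
    """Multiplicative loop-bump field on an n x n chromosome matrix."""
    L = np.ones((n, n))
    if not loops:
        return L
    ii, jj = np.indices((n, n))
    for lp in loops:
        d1 = np.maximum(np.abs(ii - lp.bin1), np.abs(jj - lp.bin2))
        d2 = np.maximum(np.abs(ii - lp.bin2), np.abs(jj - lp.bin1))
        d = np.minimum(d1, d2)  # bump and its mirror, symmetric by construction
        if lp.width_bins > 0:
            bump = 1.0 + (lp.fold - 1.0) * np.exp(-(d**2) / (2.0 * lp.width_bins**2))
        else:
            bump = np.where(d == 0, lp.fold, 1.0)
        L *= bump
    return L


def intensity_matrix(spec: MapSpec, chrom: str) -> np.ndarray:
    """Noiseless expected-count matrix Lambda for one chromosome."""
    n = spec.chromsizes.n_bins(spec.binsize_bp, chrom)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    lam = spec.depth * (d + 1.0) ** (-spec.decay_exponent)
    lam *= _loop_factor(n, [l for l in spec.loops if l.chrom == chrom])
    for td in spec.tads:
        if td.chrom == chrom:
            lam[td.start_bin : td.end_bin, td.start_bin : td.end_bin] *= td.fold
    if spec.bias is not None:
        lo, _ = spec.chromsizes.bin_span(chrom, spec.binsize_bp)
        b = spec.bias[lo : lo + n]
        lam *= np.outer(b, b)
    return lam


def simulate_contact_map(spec: MapSpec, path) -> Tuple[ContactStore, GroundTruth]:
    """Sample a contact map from ``spec`` and write it as a .cool file.

    Counts are drawn Poisson(Lambda) on the upper triangle (including the
    diagonal) and mirrored, so the written matrix is symmetric with
    expectation Lambda. The same (spec, seed) always yields an identical
    file.
    """
    rng = np.random.default_rng(spec.seed)
    lam_by_chrom: Dict[str, np.ndarray] = {}
    counts_by_chrom: Dict[str, np.ndarray] = {}
    for chrom, _ in spec.chromsizes:
        lam = intensity_matrix(spec, chrom)
        n = lam.shape[0]
        upper = np.triu(rng.poisson(lam))
        counts = upper + np.triu(upper, 1).T
        lam_by_chrom[chrom] = lam
        counts_by_chrom[chrom] = counts.astype(np.int64)
    n_bins = spec.chromsizes.n_bins(spec.binsize_bp)
    bias = spec.bias if spec.bias is not None else np.ones(n_bins)
    weights = 1.0 / bias
    store = write_contacts(counts_by_chrom, spec.chromsizes, spec.binsize_bp, weights, path)
    truth = GroundTruth(
        lam_by_chrom, counts_by_chrom, list(spec.loops), list(spec.tads),
        weights, spec.chromsizes, spec.binsize_bp,
    )
    return store, truth


def simulate_loop_calls(
    truth: GroundTruth,
    n_replicates: int,
    jitter_bins: int = 1,
    fnr: float = 0.0,
    seed: int = 0,
) -> List[PairSet]:
    """Emulate replicate loop-caller output from the true loop list.

    Each replicate contains each true loop with probability ``1 - fnr``,
    displaced by an integer offset drawn uniformly from the Manhattan
    ball of radius ``jitter_bins`` (clipped to the chromosome and kept on
    the upper triangle), with a ``count`` metadata column read from the
    sampled map at the jittered pixel. Bounding the jitter in the same
    Manhattan metric the merger clusters with gives a hard guarantee:
    two calls of one loop are at most ``2 * jitter_bins`` apart, so a
    merge radius of ``2 * jitter_bins`` bins always reunites them.
    """
    if not 0 <= fnr < 1:
        raise ValueError("fnr must be in [0, 1)")
    if jitter_bins < 0:
        raise ValueError("jitter_bins must be non-negative")
    rng = np.random.default_rng(seed)
    bs = truth.binsize_bp
    offsets = [
        (dx, dy)
        for dx in range(-jitter_bins, jitter_bins + 1)
        for dy in range(-jitter_bins, jitter_bins + 1)
        if abs(dx) + abs(dy) <= jitter_bins
    ]
    replicates = []
    for r in range(n_replicates):
        rows = []
        for lp in truth.loops:
            if fnr > 0 and rng.random() < fnr:
                continue
            nb = truth.chromsizes.n_bins(bs, lp.chrom)
            dx, dy = offsets[int(rng.integers(len(offsets)))]
            b1 = int(np.clip(lp.bin1 + dx, 0, nb - 1))
            b2 = int(np.clip(lp.bin2 + dy, 0, nb - 1))
            if b1 > b2:
                b1, b2 = b2, b1
            count = int(truth.counts[lp.chrom][b1, b2])
            length = truth.chromsizes[lp.chrom]
            rows.append(
                (
                    lp.chrom, b1 * bs, min((b1 + 1) * bs, length),
                    lp.chrom, b2 * bs, min((b2 + 1) * bs, length),
                    count,
                )
            )
        df = pd.DataFrame(rows, columns=ANCHOR_COLS + ["count"])
        replicates.append(
            PairSet(df, truth.chromsizes, source=np.full(len(df), f"rep{r + 1}", dtype=object))
        )
    return replicates
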