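"""Shared fixtures: small simulated contact maps with known ground truth.

All test data is generated at run time by the package's own simulator with
fixed seeds; nothing is read from disk fixtures.
"""

import numpy as np
import pytest

import hicpile as hp

BINSIZE = 10_000
LOOP_DISTANCE_BINS = 40
LOOP_FOLD = 5.0


def planted_loops(genome: hp.ChromSizes, stride: int = 12):
    """Well-separated fold-5 loops at a fixed 40-bin distance on each chrom."""
    loops = []
    for chrom, _ in genome:
        nb = genome.n_bins(BINSIZE, chrom)
        b1 = 10
        while b1 + LOOP_DISTANCE_BINS < nb - 10:
            loops.append(hp.Loop(chrom, b1, b1 + LOOP_DISTANCE_BINS, fold=LOOP_FOLD, width_bins=1.0))
            b1 += stride
    return loops


@pytest.fixture(scope="session")
def genome2() -> hp.ChromSizes:
    """Two-chromosome genome: 5 Mb + 3 Mb."""
    return hp.ChromSizes([("chr1", 5_000_000), ("chr2", 3_000_000)])


@pytest.fixture(scope="session")
def sim(genome2, tmp_path_factory):
    """Deeply sequenced biased map with planted loops, TADs and boundaries.

    Returns (store, truth). depth=1000 makes the median window count
    comfortably above 20, so enrichment recovery is limited by Poisson
    noise, not sparsity.
    """
    tads = [
        hp.Tad("chr1", 200, 230, fold=3.0),
        hp.Tad("chr1", 230, 270, fold=3.0),
        hp.Tad("chr1", 320, 360, fold=3.0),
        hp.Tad("chr2", 100, 140, fold=3.0),
    ]
    spec = hp.MapSpec(
        genome2,
        BINSIZE,
        decay_exponent=1.0,
        depth=1000.0,
        loops=planted_loops(genome2),
        tads=tads,
        bias=hp.make_bias(genome2.n_bins(BINSIZE), sd=0.3, seed=5),
        seed=11,
    )
    path = tmp_path_factory.mktemp("sim") / "biased.cool"
    store, truth = hp.simulate_contact_map(spec, path)
    return store, truth


@pytest.fixture(scope="session")
def store(sim) -> hp.ContactStore:
    return sim[0]


@pytest.fixture(scope="session")
def truth(sim) -> hp.GroundTruth:
    return sim[1]


@pytest.fixture(scope="session")
def plain_sim(tmp_path_factory):
    """Small featureless unbiased map for arithmetic-oracle tests."""
    genome = hp.ChromSizes([("chrA", 1_000_000)])
    spec = hp.MapSpec(genome, BINSIZE, depth=50.0, seed=3)
    path = tmp_path_factory.mktemp("plain") / "plain.cool"
    return hp.simulate_contact_map(spec, path)


def dense_lookup(truth: hp.GroundTruth, chrom: str, i: int, j: int) -> int:
    """Brute-force oracle: symmetrized count from the simulator's dense matrix."""
    return int(truth.counts[chrom][i, j])
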