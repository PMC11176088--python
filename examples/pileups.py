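"""The three all-in-one pileups: APA, aggregate TADs, boundary windows.

Simulates a map with both loops and TADs, then averages (1) 11x11 windows
around the loop pixels, (2) rescaled on-diagonal blocks around the TADs,
and (3) fixed windows centered on the TAD boundary.
"""

import tempfile
from pathlib import Path

import numpy as np

import hicpile as hp

genome = hp.ChromSizes([("chr1", 4_000_000)])
loops = [hp.Loop("chr1", 20 + 25 * k, 80 + 25 * k, fold=6.0) for k in range(8)]
tads = [hp.Tad("chr1", 250, 290, fold=3.0), hp.Tad("chr1", 290, 340, fold=3.0)]
spec = hp.MapSpec(genome, 10_000, depth=500.0, loops=loops, tads=tads, seed=5)

with tempfile.TemporaryDirectory() as d:
    store, truth = hp.simulate_contact_map(spec, Path(d) / "demo.cool")

    # APA: mean window around loop pixels; a focal center peak means the
    # loop list is globally enriched
    apa = hp.pileup_pixels([store], truth.loop_pixels_bp(), 10_000, buffer_bins=5)[0]
    center = apa.values[5, 5]
    ring = apa.values[hp.make_mask("donut", 11, inner=2, outer=5).cells].mean()
    print(f"APA: center {center:.1f} vs donut background {ring:.1f} "
          f"(ratio {center / ring:.2f})")

    # aggregate TADs: each domain plus 50% flanks, depth-normalized and
    # rescaled to 40x40 so domains of different widths align
    doms = [hp.GenomicRange(t.chrom, t.start_bin * 10_000, t.end_bin * 10_000) for t in tads]
    agg = hp.pileup_domains([store], doms, 10_000, buffer_frac=0.5, ndim=40)[0]
    inside = agg.values[15:25, 15:25].mean()
    corner = agg.values[:8, 32:].mean()
    print(f"aggregate TAD: inside-domain {inside:.2e} vs flank corner {corner:.2e}")

    # boundary pileup: window centered on the shared TAD edge; contacts
    # within each TAD (intra quadrants) exceed contacts across the edge
    b = hp.pileup_boundaries([store], [("chr1", 290 * 10_000)], 10_000, flank_bp=150_000)[0]
    n = b.shape[0]; c = n // 2
    intra = b.values[:c, :c][np.triu_indices(c, 1)].mean()
    inter = b.values[:c, c + 1:].mean()
    print(f"boundary: intra-TAD {intra:.1f} vs cross-boundary {inter:.1f} "
          f"(insulation ratio {intra / inter:.2f})")
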