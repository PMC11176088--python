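"""Merge redundant loop calls from jittered replicate call lists.

Loop callers assign the same loop to slightly different pixels across
replicates. Here three simulated replicates (1-bin jitter) are clustered
with DBSCAN at a 20 kb Manhattan radius and collapsed back to one
representative per loop, keeping every original call and its metadata.
"""

import tempfile
from pathlib import Path

import hicpile as hp

genome = hp.ChromSizes([("chr1", 2_000_000)])
loops = [hp.Loop("chr1", 30 + 20 * k, 70 + 20 * k, fold=6.0) for k in range(4)]
spec = hp.MapSpec(genome, 10_000, depth=300.0, loops=loops, seed=2)

with tempfile.TemporaryDirectory() as d:
    _, truth = hp.simulate_contact_map(spec, Path(d) / "demo.cool")
    replicates = hp.simulate_loop_calls(truth, n_replicates=3, jitter_bins=1, seed=3)
    print(f"{sum(len(r) for r in replicates)} calls across {len(replicates)} replicates, "
          f"{len(truth.loops)} true loops")

    merged = hp.merge_pairs(replicates, binsize_bp=10_000, radius_bp=20_000,
                            metric_column="count")
    print(f"merged into {merged.n_clusters} clusters "
          f"(selection: {merged.selection_record['selection']})")
    for cid, members in merged.membership.items():
        rep = merged.representatives
        print(f"  cluster {cid}: {len(members)} calls -> representative pixel "
              f"({rep.bin1[cid]}, {rep.bin2[cid]}), count {rep.df['count'][cid]}")
    # each cluster is one underlying loop; the representative is the member
    # with the highest observed count, and all 12 original calls remain
    # addressable through merged.originals / merged.membership
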