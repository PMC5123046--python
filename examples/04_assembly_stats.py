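"""Assembly contiguity statistics, recovery rate and novel regions.

Fragments a toy chromosome into scaffolds, prints the Nxx/Lxx table (the
fragment length at which fragments that long or longer reach xx% of the
assembly, and how many there are), computes the recovery rate of a
reference by alignment intervals, and calls novel regions from an
unmapped-read depth track.
"""

import numpy as np

from consensusref import SequenceSet, assembly_stats, fragment_assembly, recovery_rate
from consensusref.assembly_eval import CoverageTrack, novel_regions

rng = np.random.default_rng(11)
reference = SequenceSet({"chr1": "".join(rng.choice(list("ACGT"), size=300_000))})
sim = fragment_assembly(reference, 12, seed=11)

stats = assembly_stats(sim.scaffolds, min_len=200)
print(f"{stats.n_fragments} scaffolds, total {stats.total_length:,} bp, "
      f"longest {stats.longest:,} bp, gaps {stats.gap_percent:.2f}%")
for x in sorted(stats.nxx):
    print(f"  N{x} = {stats.nxx[x]:>7,} bp   L{x} = {stats.lxx[x]}")

# recovery: how much of the reference do the scaffold placements cover?
intervals = {"chr1": list(zip(sim.truth.t_start, sim.truth.t_end))}
print(f"reference recovery rate: {recovery_rate(intervals, reference):.1f}% "
      "(non-gap bases covered by alignments)")

depth = np.zeros(300_000, dtype=int)
depth[1_000:1_250] = 4   # 250 bp at depth 4: novel
depth[5_000:5_090] = 6   # 90 bp: below the 100 bp length rule
track = CoverageTrack({"chr1": depth})
regions = novel_regions(track, min_depth=3, min_len=100)
print(f"novel regions (depth >= 3 over >= 100 bp): {regions['chr1']}")
print("only the 250 bp run qualifies; the 90 bp run fails the length rule.")
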