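"""Build a population consensus reference from a simulated cohort.

Simulates a 50 kb reference genotyped in 40 diploids (25 male, 15 female),
then substitutes the cohort-major allele at every SNV site where it differs
from the reference and every indel carried by more than 40 of 80 haploids.
"""

from consensusref import PopulationModel, build_consensus, simulate_cohort

sim = simulate_cohort(PopulationModel(), seed=1)
result = build_consensus(sim.reference, sim.records, sim.scheme)

applied = result.report[result.report.status == "applied"]
n_snv = int((applied.kind == "SNV").sum())
n_indel = int((applied.kind == "INDEL").sum())
chrom = sim.model.chrom

print(f"cohort: {len(sim.samples)} diploids, "
      f"{len(sim.records)} variant sites on a {len(sim.reference[chrom]):,} bp reference")
print(f"substituted {n_snv} SNVs (cohort-major allele differs from reference)")
print(f"substituted {n_indel} indels (haploid support > 40 of 80)")
print(f"consensus length: {len(result.consensus[chrom]):,} bp "
      f"(indel substitutions shift coordinates; the chain records the offsets)")
print(f"chain blocks on {chrom}: {len(result.chain.blocks[chrom])}")
print()
print("first three substitutions with their haploid support:")
print(applied.head(3).to_string(index=False))
# Each row is one reference edit: 'support' of 'called' haploids carried the
# substituted allele, out of a chromosome capacity of 'capacity' haploids.
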