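"""Lift a held-out individual's calls onto the consensus and compare.

A new diploid drawn from the same population is genotyped against the
baseline reference; its calls are lifted through the chain onto the
consensus, where genotypes are re-expressed against the substituted bases.
Homozygous calls largely vanish: the consensus already carries the
population-major allele.
"""

from consensusref import PopulationModel, build_consensus, simulate_cohort
from consensusref.liftover import lift_records
from consensusref.synthetic import simulate_individual
from consensusref.variant_compare import (
    calls_from_records,
    count_by_zygosity_and_class,
    reference_specific_variants,
)

sim = simulate_cohort(PopulationModel(), seed=1)
result = build_consensus(sim.reference, sim.records, sim.scheme)

individual = simulate_individual(sim, seed=2024)
calls_base = calls_from_records(individual, "IND", "baseline")
lifted, rejects = lift_records(result.chain, result.consensus, individual)
calls_cons = calls_from_records(lifted, "IND", "consensus")

for label, calls in (("baseline", calls_base), ("consensus", calls_cons)):
    table = count_by_zygosity_and_class(calls)["IND"]
    print(f"against {label:9s}: "
          f"hom SNV {table[('HOM', 'SNV')]:4d}  hom indel {table[('HOM', 'INDEL')]:3d}  "
          f"het SNV {table[('HET', 'SNV')]:4d}  het indel {table[('HET', 'INDEL')]:3d}")

shared, base_only, cons_only = reference_specific_variants(
    calls_base, calls_cons, result.chain, result.consensus)
print(f"\nshared calls: {len(shared)}; baseline-specific: {len(base_only)}; "
      f"consensus-specific: {len(cons_only)}; unmappable sites: {len(rejects)}")
print("baseline-specific calls are dominated by homozygous major alleles the")
print("consensus absorbed; heterozygous calls survive the reference switch.")
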