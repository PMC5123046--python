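# consensusref

Toolkit for building and evaluating **population consensus reference
genomes** — references in which the bases of a single-donor assembly are
replaced by the most frequent alleles of a cohort, removing donor-specific
bias so that individuals from the same population can be genotyped with far
fewer spurious homozygous calls.

It is written for genomicists who work with ethnicity-specific or personal
reference genomes and need the surrounding machinery to be auditable:
which substitutions were made and on what haploid support, how coordinates
moved, and how variant and structural-variant (SV) call sets compare across
references.

## What it computes

**Consensus construction.** Given a baseline reference (FASTA) and a cohort
VCF with GT genotypes, the builder tallies allele support per site over the
called haploids and substitutes:

* at SNV sites, the cohort-major allele `argmax_a n_a` whenever it differs
  from the reference base (ties keep the reference);
* indels whose supporting haploid count *k* strictly exceeds half the
  chromosome's haploid capacity *H* (`k > H/2`, i.e. over 40 of 80
  autosomal haploids for a 40-diploid cohort; sex chromosomes use
  sex-specific capacities — 2·n_females on X, n_males on Y).

Applying the resulting edit script yields the consensus FASTA plus a UCSC
**lift-over chain** describing the induced coordinate map, so calls made
against either reference can be projected onto the other with their alleles
re-expressed against the new reference base.

**Comparison machinery.**

* variant-set comparison across references: restriction to mutually
  alignable regions, per-individual homozygous/heterozygous × SNV/indel
  count tables, reference-specific variant decomposition, sharedness
  spectra;
* SV concordance: two SVs are the same iff they have the same type and are
  *reciprocally 50% covered*; exclusive sharing groups across labelled
  assemblies via single-linkage clustering; novelty against known-SV
  databases; two-group frequency enrichment (Fisher's exact test,
  p < 0.05);
* misassembly filtering by the **S/P ratio**: an SV region whose
  single-end/paired read ratio is significantly inflated versus the
  genome-wide ratio (Fisher's exact test, p < 0.001) is discarded as
  spurious;
* assembly statistics (Nxx/Lxx, gap fraction, alignment recovery rate,
  novel regions with length ≥ 100 bp at unmapped-read depth ≥ 3) and
  rule-based chromosome building from scaffold anchors with AGP 2.0 output.

**Synthetic data.** Every input has a seeded generator with planted ground
truth (diploid cohorts under Hardy–Weinberg, SV universes with known
sharing structure, S/P read-count profiles, scaffold fragmentations), so
the full pipeline is testable offline.

## Worked example

```bash
python examples/01_build_consensus.py
```

```
cohort: 40 diploids, 2200 variant sites on a 50,000 bp reference
substituted 1000 SNVs (cohort-major allele differs from reference)
substituted 89 indels (haploid support > 40 of 80)
consensus length: 50,021 bp (indel substitutions shift coordinates; the chain records the offsets)
chain blocks on chr1: 90

first three substitutions with their haploid support:
chrom  pos kind ref alt  support  called  capacity  status reason
 chr1  120  SNV   G   C       69      78        80 applied
 chr1  160  SNV   A   C       51      78        80 applied
 chr1  180  SNV   A   G       53      76        80 applied
```

Each report row is one reference edit: at chr1:120 the cohort carried `C`
on 69 of 78 called haploids (capacity 80; two haploids uncalled), so the
consensus substitutes `G → C`. The 89 indel substitutions change the
sequence length, which is why the consensus is 21 bp longer and the chain
has 90 aligned blocks.

Lifting a held-out individual's calls onto the consensus
(`examples/02_liftover_and_compare.py`) shows the point of the exercise:

```
against baseline : hom SNV  586  hom indel  61  het SNV  814  het indel  82
against consensus: hom SNV  198  hom indel  43  het SNV  814  het indel  70
```

Homozygous calls collapse (the consensus already carries the population
major allele) while heterozygous calls are untouched — the same qualitative
behaviour that motivates ethnicity-matched consensus references.

The other examples cover SV concordance and S/P filtering
(`03_sv_concordance.py`), assembly statistics and novel regions
(`04_assembly_stats.py`), and chromosome building with AGP round-trip
(`05_chromosome_building.py`). A thin CLI wraps the same functions:
`consensusref build|liftover|compare|sv-compare|asm-stats|build-chrom|simulate`.

## Layout

```
src/consensusref/
  io_formats.py       FASTA / VCF / chain / AGP / TSV readers and writers
  consensus.py        allele tallies, substitution selection, edit application
  liftover.py         chain model, position/interval/variant mapping
  variant_compare.py  cross-reference call-set comparison
  sv_compare.py       SV identity, sharing, S/P filter, enrichment
  assembly_eval.py    Nxx/Lxx, gap %, recovery rate, novel regions
  chrom_builder.py    scaffold placement, gap estimation, AGP emission
  synthetic.py        seeded generators with planted ground truth
  cli.py              thin click CLI over the library
```

See `docs/methods.md` for the model, its assumptions and the numerical
conventions.
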