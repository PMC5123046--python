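# Methods

## The consensus-reference model

A consensus (variome) reference replaces the bases of a single-donor
assembly with the alleles most frequent in a population cohort. The model
of the cohort is deliberately simple: at each site the cohort contributes a
number of *called haploids* (two per diploid sample with a genotype, fewer
when genotypes are missing), and substitution decisions are made from
haploid counts alone — no imputation, no weighting by quality.

**SNV rule.** At a site with reference base *r* and haploid counts
`n_a` over all observed bases (reference included), the consensus carries
`argmax_a n_a` when that argmax is unique and differs from *r*. Ties —
including an exact 50/50 ref/alt split — keep the reference, because a tie
has no unique most-frequent allele. The denominator is the *called*
haploids: missing genotypes shrink it.

**Indel rule.** An indel is substituted when its supporting haploid count
strictly exceeds half the chromosome's haploid *capacity* (not the called
count): more than 40 of 80 autosomal haploids for a 40-diploid cohort.
This is an absolute-count rule, so heavy missingness makes indel
substitution conservative, which is the intended behaviour for
length-changing edits. The threshold fraction is a parameter
(`SubstitutionPolicy.indel_fraction`, default 0.5) because different
cohorts (e.g. a low-coverage public panel) may warrant different
stringency.

**Ploidy.** Capacity is per chromosome and derives from the cohort's sex
composition: autosomes 2·n_samples; X counted from females only
(2·n_females); Y from males only (1 each). For the default cohort of 40
(25 male / 15 female) this gives 80 / 30 / 25 haploids. Pseudo-autosomal
regions receive no special treatment; if needed, region-specific overrides
can be expressed by splitting the input upstream. Genotypes whose arity
conflicts with the scheme (a haploid call on an autosome, any call from a
zero-capacity sample) are hard errors, not warnings — they indicate the
sex map is wrong.

**Normalisation.** Cohort VCFs mix indel representations, so every allele
is parsimony-trimmed and pure indels are left-aligned against the
reference before tallying; identical events then aggregate across records.
Multiallelic records are decomposed per allele; the SNV comparison is over
all observed bases plus the reference. One consequence worth knowing: in a
record mixing an SNV alt with a length-changing alt, a haploid carrying
the length-changing allele determines no base at the SNV position and is
excluded from that position's called denominator.

**Conflicts.** Edits are selected SNVs first, then indels ordered by
position; any indel whose reference span overlaps a previously accepted
edit is dropped and reported in the edit report (status `dropped`). The
report lists every substitution with its haploid support, called count and
capacity, so every decision is auditable.

## Coordinate mapping

Applying the edit script yields the consensus and, in the same pass, a
chain of aligned blocks: same-length (SNV) edits never interrupt a block;
length-changing edits close the block and open a source-side gap
(deletion) or target-side gap (insertion). The chain is exact by
construction — it is derived from the known edits rather than re-discovered
by whole-genome alignment, which is appropriate because substitution-
induced chains cannot rearrange or change strand (same-chromosome,
forward-strand only, enforced).

Positions map affinely within blocks; positions in deleted spans are
UNMAPPED, and the number of unmapped source positions equals the chain's
total source-gap length. Because edits are left-aligned, an inserted run
sits immediately to the left of the image of its insertion point; this is
the only convention under which backward-then-forward mapping is the
identity on every mappable position, which the tests check exhaustively.

Variant lifting maps the whole reference span of a record; spans that
cross a block edge are UNMAPPED rather than truncated, since truncation
silently changes alleles. After mapping, the reference allele is re-read
from the target sequence; when it changed (the consensus absorbed an
allele) all alleles and genotypes are re-expressed against the new
reference base and the record is flagged `REF_CHANGED`. A formerly hom-ALT
genotype at a substituted site becomes hom-REF — the call vanishes, which
is exactly the mechanism behind the homozygous-call reduction.

## Cross-reference comparison

Call sets from one individual against two references are compared only
after lift-over and allele re-expression; identity requires matching
position plus matching normalised, genotype-carried alleles (a hom call is
two copies of the allele, so zygosity participates in identity, preventing
hom/het conflation). Region restriction is per variant span by default
(every spanned base must map through every chain); a position-only mode
exists because the alternative reading of "shared regions" is defensible
and the difference is auditable through the rejects list.

## SV concordance and the S/P filter

Two SVs are the same iff same type and *reciprocal 50% coverage*: the
intersection covers at least half of each record's own span, computed in
exact integer arithmetic so the boundary counts (`2*overlap >= len` on
both sides). Insertions have zero reference span, so reciprocal span
overlap is undefined for them; the implemented surrogate — breakpoints
within a 1,000 bp window (configurable) plus reciprocal length ratio
≥ 0.5 — is an interpretation, and deliberately a conservative one.

Sharing decomposition is single-linkage clustering over this identity
(connected components, hence order-independent); each cluster is assigned
to the exact set of assemblies that contributed a record, giving the
exclusive sharing groups. Single linkage is the weakest assumption that
still yields a partition.

The S/P filter compares a region's single-end vs properly-paired read
counts with the genome-wide counts in a 2×2 Fisher's exact test. A region
is discarded only when the two-sided p-value is below 0.001 *and* its
single-end fraction is the inflated side — spurious, misassembly-derived
SVs attract wrongly mapped single-end reads, whereas a deflated ratio is
no evidence of misassembly. The two-sided-test-plus-direction construction
is used because only the significance level and the direction rationale
are specified by the procedure the filter reproduces; a one-sided variant
would be very slightly more permissive and is available via
`fisher_exact(..., alternative=...)`.

`fisher_exact` itself sums hypergeometric point probabilities not
exceeding the observed one (relative tolerance 1e-7 on the comparison):
exact integer combinatorics up to a grand total of 2,000, and a vectorised
log-gamma evaluation above that, where integer weights would be
astronomically large. Tests check both paths against an independent
enumeration oracle and against `scipy.stats.fisher_exact`.

## Assembly statistics and chromosome building

Nxx is the largest fragment length L such that fragments ≥ L sum to at
least xx% of the included total; Lxx counts those fragments. The
denominator is the total of fragments passing the inclusion cutoff
(default ≥ 200 bp); gap percentages are offered against either the
assembly total or a supplied expected genome size, because published
tables use both conventions and the choice must be explicit. Recovery rate
is the union of alignment intervals intersected with the reference's
non-gap mask, divided by the non-gap length. Novel regions are maximal
runs of unmapped-read depth ≥ 3 with length ≥ 100 bp, both thresholds
inclusive, no merging across below-threshold bases; producing the
unmapped-read depth track (sequential alignment, contaminant screening)
is upstream of this package's contract.

Chromosome building follows fixed rules: a primary pass places scaffolds
(≥ 10 kb) with ≥ 7 anchors on a single best chromosome, a rescue pass
re-admits leftovers at ≥ 4 anchors (optionally from a re-aligned anchor
set), and small scaffolds place only on mapping-quality-254 alignments.
Conflicting multi-chromosome placements resolve to the highest anchor
count; an exact tie leaves the scaffold unplaced with a warning.
Orientation is a majority vote over anchor strands (tie → plus, with a
warning). Gaps between ordered placements are the reference-coordinate
distance when positive; overlapping *or exactly abutting* placements get a
fixed 10 kb gap — AGP gap rows must have positive length, so zero-distance
abutment is folded into the overlap rule. Chromosomes get 10 kb N pads at
both ends as telomeric stand-ins; unplaced scaffolds concatenate into
`chrUn` with 10 kb spacers (the spacer mirrors the pad convention). The
emitted AGP rebuilds the FASTA byte-for-byte, and the test suite uses that
reconstruction as its oracle.

## What the synthetic data does and does not emulate

The generators reproduce the *structure* of the real study inputs: a
cohort of 40 diploids (25 male / 15 female) giving the 80/30/25 haploid
arithmetic, Hardy–Weinberg genotypes at planted site frequencies
(SNV alt frequencies U(0.1, 0.9); indel frequencies U(0.3, 0.7) so support
spans the substitution threshold; 2% genotype missingness), indel sites
with supports of exactly 40 and 41 planted to pin both sides of the
over-half boundary, SV universes with known exclusive-sharing structure
including pairs at exactly 50% and at 49% reciprocal overlap, S/P
profiles at the genome-wide single-end rate vs a 10× inflated rate with at
least 100 reads per region, and scaffold fragmentations with perfect
maximum-quality anchors.

They do **not** emulate sequencing reads or their error processes, linkage
disequilibrium, repeat structure, alignment ambiguity, or caller-specific
artefacts. Passing tests therefore demonstrate that the *rules* are
implemented exactly and that the pipeline's algebra (edit → chain → lift →
re-expression) is self-consistent — not that any particular real-data
number would be reproduced, since those depend on terabase-scale read data
and real population structure.

Default problem sizes (50 kb reference, 2,200 sites, 200-pair chain
oracles, 100 hold-out replicates, 100 fragmentations) were chosen as the
smallest scales at which every rule, boundary case and conservation law is
exercised with comfortable statistical margins; the full suite runs in
seconds.

## Numerical and degenerate-input conventions

* All internal coordinates are 0-based half-open; VCF and AGP convert at
  the format boundary only.
* An all-zero contingency table has p = 1 by convention (with a warning);
  an SV region with zero paired reads counts as maximal S/P inflation.
* Empty cohort input produces an empty edit script, not an error; an edit
  whose reference span disagrees with the baseline sequence aborts with
  the offending position.
* Sequence alphabet is strictly {A, C, G, T, N}, uppercase after reading;
  anything else is rejected at parse time.
* Seeded generators are pure functions of (model, seed) and are
  byte-reproducible; nothing reads global random state.

## Known limitations

* Chains only describe substitution-induced edits; general whole-genome
  alignment chains (rearrangements, strand flips, cross-chromosome maps)
  are out of scope.
* The insertion-identity window and length-ratio surrogate for reciprocal
  overlap is an interpretation; results for insertion-heavy SV sets should
  be read with that in mind.
* Variant identity after lift-over requires exact normalised-allele
  equality; near-miss representations that survive normalisation (e.g.
  complex MNP vs SNV decompositions from different callers) count as
  reference-specific.
* The builder assumes cohort records at a site fit in one VCF record per
  event; the same normalised indel arriving in several records aggregates
  support but takes the maximum called denominator across them.
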