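"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of its model and seed (a single
explicitly passed NumPy generator seed; no hidden global state), producing
byte-reproducible outputs in the toolkit's standard formats.  The defaults
emulate the study conditions the toolkit is built around: a 50 kb toy
reference with 2,000 SNV and 200 indel sites genotyped in a cohort of 40
diploids (25 male, 15 female), so the haploid arithmetic (80 autosomal
haploids, 30 female-X, 25 male-Y) matches the real cohort exactly; SV sets
with planted exclusive-sharing structure; single-end/paired read-count
profiles for authentic versus misassembly-derived SVs; and scaffold
fragmentations of a toy chromosome with perfect anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .consensus import PloidyScheme, normalize_variant
from .io_formats import (
    Anchor,
    SequenceSet,
    SVRecord,
    VariantRecord,
    revcomp,
    write_anchors,
    write_fasta,
    write_sv_tsv,
    write_vcf,
)
from .sv_compare import SPCounts

_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# Diploid cohort
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Study-design parameters for the simulated cohort.

    Alt-allele population frequencies are drawn uniformly from
    ``snv_freq_range`` / ``indel_freq_range``; genotypes are sampled per
    site under Hardy-Weinberg.  The first ``len(planted_indel_supports)``
    indel sites are planted with exactly those haploid support counts
    (defaults 40 and 41 — both sides of the over-half-of-80 substitution
    boundary).  Sex-chromosome contigs are opt-in so the autosomal headline
    condition stays exactly 50 kb / 2,200 sites.
    """

    ref_length: int = 50_000
    n_snv_sites: int = 2_000
    n_indel_sites: int = 200
    n_samples: int = 40
    n_male: int = 25
    missing_rate: float = 0.02
    snv_freq_range: Tuple[float, float] = (0.1, 0.9)
    indel_freq_range: Tuple[float, float] = (0.3, 0.7)
    planted_indel_supports: Tuple[int, ...] = (40, 41)
    max_indel_len: int = 6
    chrom: str = "chr1"
    sex_chroms: bool = False
    x_length: int = 10_000
    y_length: int = 6_000
    n_x_sites: int = 40
    n_y_sites: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.n_male <= self.n_samples:
            raise ValueError("n_male must be within the cohort size")
        for lo, hi in (self.snv_freq_range, self.indel_freq_range):
            if not 0 <= lo <= hi <= 1:
                raise ValueError("frequency ranges must lie in [0, 1]")

    @property
    def n_female(self) -> int:
        return self.n_samples - self.n_male


@dataclass
class CohortSim:
    """A simulated cohort: reference, VCF-style records and the truth table.

    ``truth`` has one row per planted site with its normalised coordinates,
    realised haploid support among called haploids, the empirical major
    allele (ties resolved to the reference, as the builder does) and the
    substitution ground truth.
    """

    reference: SequenceSet
    records: List[VariantRecord]
    samples: List[str]
    scheme: PloidyScheme
    truth: pd.DataFrame
    model: PopulationModel
    seed: int

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": outdir / "reference.fa",
            "cohort": outdir / "cohort.vcf",
            "truth": outdir / "truth.tsv",
            "sexes": outdir / "sexes.tsv",
        }
        write_fasta(self.reference, paths["reference"])
        write_vcf(self.records, self.reference.lengths, paths["cohort"],
                  samples=self.samples)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["sexes"], "w") as fh:
            fh.write("sample\tsex\n")
            for s in self.samples:
                fh.write(f"{s}\t{self.scheme.sexes[s]}\n")
        return paths


def _genotypes_for_support(
    samples: Sequence[str], support: int, arity: int = 2
) -> Dict[str, Tuple[int, ...]]:
    """Deterministic genotypes realising an exact haploid support count."""
    if support > arity * len(samples):
        raise ValueError("support exceeds haploid capacity")
    gts = {}
    remaining = support
    for s in samples:
        take = min(arity, remaining)
        gts[s] = tuple([1] * take + [0] * (arity - take))
        remaining -= take
    return gts


def _draw_site(
    rng: np.random.Generator,
    samples: Sequence[str],
    freq: float,
    missing_rate: float,
    arity: int = 2,
) -> Tuple[Dict[str, Tuple[Optional[int], ...]], int, int]:
    """Hardy-Weinberg genotypes; returns (genotypes, alt support, called)."""
    gts: Dict[str, Tuple[Optional[int], ...]] = {}
    support = called = 0
    draws = rng.random((len(samples), arity)) < freq
    missing = rng.random(len(samples)) < missing_rate
    for i, s in enumerate(samples):
        if missing[i]:
            gts[s] = tuple([None] * arity)
            continue
        gt = tuple(int(v) for v in draws[i])
        gts[s] = gt
        support += sum(gt)
        called += arity
    return gts, support, called


def simulate_cohort(model: PopulationModel, seed: int = 0) -> CohortSim:
    """Simulate a diploid cohort over a toy reference with planted truth."""
    rng = np.random.default_rng(seed)
    sequences = {model.chrom: _random_sequence(rng, model.ref_length)}
    samples = [f"S{i:02d}" for i in range(model.n_samples)]
    sexes = {s: ("M" if i < model.n_male else "F") for i, s in enumerate(samples)}
    scheme = PloidyScheme(sexes)

    candidates = np.arange(100, model.ref_length - 100, 20)
    n_sites = model.n_snv_sites + model.n_indel_sites
    if n_sites > candidates.size:
        raise ValueError("reference too short for the requested site count")
    chosen = rng.choice(candidates, size=n_sites, replace=False)
    kinds = np.array(["SNV"] * model.n_snv_sites + ["INDEL"] * model.n_indel_sites)
    rng.shuffle(kinds)
    order = np.argsort(chosen)
    site_plan = list(zip(chosen[order], kinds[order]))

    records: List[VariantRecord] = []
    truth_rows = []
    indel_index = 0
    seq = sequences[model.chrom]
    for pos, kind in site_plan:
        pos = int(pos)
        if kind == "SNV":
            ref_base = seq[pos]
            alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            freq = float(rng.uniform(*model.snv_freq_range))
            gts, support, called = _draw_site(rng, samples, freq, model.missing_rate)
            records.append(VariantRecord(model.chrom, pos, ref_base, (alt_base,), gts))
            major = alt_base if 2 * support > called else ref_base
            truth_rows.append(
                (model.chrom, pos, ref_base, alt_base, "SNV", freq, support,
                 called, 2 * model.n_samples, major, major != ref_base)
            )
        else:
            is_del = bool(rng.random() < 0.5)
            k = int(rng.integers(1, model.max_indel_len + 1))
            if is_del:
                event = (pos, seq[pos:pos + k], "")
            else:
                event = (pos, "", _random_sequence(rng, k))
            npos, nref, nalt = normalize_variant(seq, *event)
            if indel_index < len(model.planted_indel_supports):
                support = int(model.planted_indel_supports[indel_index])
                gts = _genotypes_for_support(samples, support)
                called = 2 * model.n_samples
                freq = support / (2 * model.n_samples)
            else:
                freq = float(rng.uniform(*model.indel_freq_range))
                gts, support, called = _draw_site(rng, samples, freq, model.missing_rate)
            indel_index += 1
            # anchored VCF representation (anchor base immediately left of the event)
            anchor = pos - 1
            if is_del:
                vref = seq[anchor:pos + k]
                valt = seq[anchor]
            else:
                vref = seq[anchor]
                valt = seq[anchor] + event[2]
            records.append(VariantRecord(model.chrom, anchor, vref, (valt,), gts))
            substituted = support > model.n_samples  # strict > half of 2n capacity
            truth_rows.append(
                (model.chrom, npos, nref, nalt, "INDEL", freq, support,
                 called, 2 * model.n_samples, None, substituted)
            )

    if model.sex_chroms:
        _add_sex_chrom_sites(model, rng, sequences, samples, sexes, records, truth_rows)

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "kind", "freq", "support",
                 "called", "capacity", "major_allele", "substituted"],
    )
    return CohortSim(SequenceSet(sequences), records, samples, scheme, truth,
                     model, seed)


def _add_sex_chrom_sites(model, rng, sequences, samples, sexes, records, truth_rows):
    """Plant SNV sites on toy X (female diploids only) and Y (male haploids)."""
    females = [s for s in samples if sexes[s] == "F"]
    males = [s for s in samples if sexes[s] == "M"]
    for chrom, length, n_sites, carriers, arity, capacity in (
        ("chrX", model.x_length, model.n_x_sites, females, 2, 2 * len(females)),
        ("chrY", model.y_length, model.n_y_sites, males, 1, len(males)),
    ):
        if not carriers or n_sites == 0:
            continue
        sequences[chrom] = _random_sequence(rng, length)
        seq = sequences[chrom]
        positions = np.sort(rng.choice(np.arange(50, length - 50, 10),
                                       size=n_sites, replace=False))
        for pos in positions:
            pos = int(pos)
            ref_base = seq[pos]
            alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            freq = float(rng.uniform(*model.snv_freq_range))
            gts, support, called = _draw_site(rng, carriers, freq,
                                              model.missing_rate, arity=arity)
            for s in samples:
                if s not in gts:
                    gts[s] = tuple([None] * arity)
            records.append(VariantRecord(chrom, pos, ref_base, (alt_base,), gts))
            major = alt_base if 2 * support > called else ref_base
            truth_rows.append((chrom, pos, ref_base, alt_base, "SNV", freq,
                               support, called, capacity, major, major != ref_base))


def simulate_individual(
    sim: CohortSim, seed: int, name: str = "IND"
) -> List[VariantRecord]:
    """Draw a held-out diploid from the cohort's site frequencies.

    Returns one single-sample record per planted autosomal site, including
    hom-reference genotypes — after lift-over to the consensus those can
    re-express as variant calls when the consensus absorbed the major
    allele, so they must travel with the call set.
    """
    rng = np.random.default_rng(seed)
    records: List[VariantRecord] = []
    autosome = sim.model.chrom
    # truth rows and cohort records are appended in lockstep by the generator
    for rec, row in zip(sim.records, sim.truth.itertuples(index=False)):
        if row.chrom != autosome:
            continue
        gt = tuple(int(v) for v in rng.random(2) < row.freq)
        records.append(
            VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alts, {name: gt})
        )
    return records


# ---------------------------------------------------------------------------
# SV universe with planted sharing
# ---------------------------------------------------------------------------

DEFAULT_LABELS = ("asm1", "asm2", "asm3", "asm4", "asm5")

#: Default exclusive-sharing design over five assemblies: subset -> cluster count.
DEFAULT_SHARING_DESIGN: Dict[FrozenSet[str], int] = {
    frozenset({lab}): 6 for lab in DEFAULT_LABELS
}
DEFAULT_SHARING_DESIGN.update({
    frozenset({"asm1", "asm2"}): 4,
    frozenset({"asm2", "asm3"}): 3,
    frozenset({"asm1", "asm3"}): 2,
    frozenset({"asm4", "asm5"}): 3,
    frozenset({"asm3", "asm4"}): 2,
    frozenset({"asm1", "asm2", "asm3"}): 3,
    frozenset({"asm3", "asm4", "asm5"}): 2,
    frozenset({"asm1", "asm2", "asm3", "asm4"}): 1,
    frozenset(DEFAULT_LABELS): 2,
})

_SV_TYPES = ("DEL", "INS", "INV")


def simulate_sv_universe(
    design: Optional[Mapping[FrozenSet[str], int]] = None,
    seed: int = 0,
    plant_boundary: bool = True,
    chrom: str = "chr1",
    spacing: int = 10_000,
) -> Tuple[Dict[str, List[SVRecord]], Dict[FrozenSet[str], int]]:
    """Plant SV clusters with known exclusive sharing across labelled sets.

    Shared copies of a cluster are jittered within the reciprocal-50%
    tolerance; clusters are spaced so distinct clusters can never match.
    With ``plant_boundary`` two extra deletion pairs sit exactly at the 50%
    reciprocal-overlap boundary (a match) and just below it at 49% (two
    singletons).  Returns the labelled sets and the truth group counts.
    """
    rng = np.random.default_rng(seed)
    design = dict(design) if design is not None else dict(DEFAULT_SHARING_DESIGN)
    labels = sorted({lab for subset in design for lab in subset})
    if len(labels) < 2:
        raise ValueError("sharing design must span at least two labels")
    sets: Dict[str, List[SVRecord]] = {lab: [] for lab in labels}
    truth: Dict[FrozenSet[str], int] = {}

    slot = 0
    for subset in sorted(design, key=lambda s: (len(s), sorted(s))):
        for _ in range(design[subset]):
            base = 100_000 + slot * spacing
            slot += 1
            sv_type = _SV_TYPES[slot % len(_SV_TYPES)]
            length = int(rng.integers(200, 2_000))
            for lab in sorted(subset):
                if sv_type == "INS":
                    start = base + int(rng.integers(-200, 201))
                    lng = max(50, int(length * rng.uniform(0.8, 1.25)))
                    sets[lab].append(SVRecord(chrom, start, start, "INS", lng, lab))
                else:
                    shift = int(rng.integers(-(length // 5), length // 5 + 1))
                    start = base + shift
                    sets[lab].append(
                        SVRecord(chrom, start, start + length, sv_type, length, lab)
                    )
            truth[frozenset(subset)] = truth.get(frozenset(subset), 0) + 1

    if plant_boundary:
        a, b = labels[0], labels[1]
        base = 100_000 + slot * spacing
        # exact reciprocal 50%: overlap 100 of two 200 bp deletions -> same SV
        sets[a].append(SVRecord(chrom, base, base + 200, "DEL", 200, a))
        sets[b].append(SVRecord(chrom, base + 100, base + 300, "DEL", 200, b))
        truth[frozenset({a, b})] = truth.get(frozenset({a, b}), 0) + 1
        base += spacing
        # 49% overlap -> two distinct singletons
        sets[a].append(SVRecord(chrom, base, base + 200, "DEL", 200, a))
        sets[b].append(SVRecord(chrom, base + 102, base + 302, "DEL", 200, b))
        truth[frozenset({a})] = truth.get(frozenset({a}), 0) + 1
        truth[frozenset({b})] = truth.get(frozenset({b}), 0) + 1
    return sets, truth


# ---------------------------------------------------------------------------
# S/P read-count profiles
# ---------------------------------------------------------------------------

def simulate_sp_counts(
    n_authentic: int = 500,
    n_spurious: int = 500,
    genome: SPCounts = SPCounts(1_000, 99_000),
    inflation: float = 10.0,
    mean_reads: int = 200,
    min_reads: int = 100,
    seed: int = 7,
) -> Tuple[pd.DataFrame, SPCounts]:
    """Draw per-region S/P read counts for authentic and spurious SVs.

    Authentic regions draw their single-end fraction at the genome-wide
    rate; spurious (misassembly-derived) regions at ``inflation`` times it.
    """
    if inflation < 1:
        raise ValueError("inflation must be >= 1")
    rng = np.random.default_rng(seed)
    p_genome = genome.single / (genome.single + genome.paired)
    p_spur = min(0.99, inflation * p_genome)
    rows = []
    for i in range(n_authentic + n_spurious):
        authentic = i < n_authentic
        total = max(min_reads, int(rng.poisson(mean_reads)))
        single = int(rng.binomial(total, p_genome if authentic else p_spur))
        rows.append((f"sv{i:04d}", single, total - single, authentic))
    df = pd.DataFrame(rows, columns=["region", "single", "paired", "authentic"])
    return df, genome


# ---------------------------------------------------------------------------
# Scaffold fragmentation
# ---------------------------------------------------------------------------

@dataclass
class FragmentSim:
    """A fragmented toy chromosome with perfect anchors and the truth layout."""

    scaffolds: SequenceSet
    anchors: List[Anchor]
    truth: pd.DataFrame  # columns: order, scaffold, orientation, t_start, t_end
    chrom: str

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"scaffolds": outdir / "scaffolds.fa",
                 "anchors": outdir / "anchors.tsv",
                 "truth": outdir / "truth.tsv"}
        write_fasta(self.scaffolds, paths["scaffolds"])
        write_anchors(self.anchors, paths["anchors"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def fragment_assembly(
    reference: SequenceSet,
    n_scaffolds: int,
    seed: int = 0,
    anchors_per_scaffold: int = 8,
    min_fragment: int = 10_000,
) -> FragmentSim:
    """Cut one chromosome into oriented scaffolds with perfect anchors.

    Fragments are contiguous and non-overlapping; each gets
    ``anchors_per_scaffold`` maximum-quality anchors tiling it, with
    scaffold coordinates flipped for minus-orientation fragments.  The
    presentation order of the scaffold FASTA is shuffled so recovery of the
    true order is non-trivial.
    """
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    if len(reference) != 1:
        raise ValueError("fragment_assembly expects a single-chromosome reference")
    rng = np.random.default_rng(seed)
    chrom = reference.names[0]
    seq = reference[chrom]
    extra = len(seq) - n_scaffolds * min_fragment
    if extra < 0:
        raise ValueError("reference too short for n_scaffolds at min_fragment")
    lengths = min_fragment + rng.multinomial(extra, [1 / n_scaffolds] * n_scaffolds)

    scaffolds = {}
    anchors: List[Anchor] = []
    truth_rows = []
    start = 0
    for i, flen in enumerate(map(int, lengths)):
        name = f"scaffold_{i + 1:03d}"
        end = start + flen
        orientation = "+" if rng.random() < 0.5 else "-"
        frag = seq[start:end]
        scaffolds[name] = frag if orientation == "+" else revcomp(frag)
        bounds = np.linspace(0, flen, anchors_per_scaffold + 1).astype(int)
        for a0, a1 in zip(bounds, bounds[1:]):
            if orientation == "+":
                s0, s1 = int(a0), int(a1)
            else:
                s0, s1 = flen - int(a1), flen - int(a0)
            anchors.append(Anchor(name, chrom, s0, s1,
                                  start + int(a0), start + int(a1),
                                  orientation, 254))
        truth_rows.append((i, name, orientation, start, end))
        start = end

    presented = {}
    for idx in rng.permutation(n_scaffolds):
        name = f"scaffold_{int(idx) + 1:03d}"
        presented[name] = scaffolds[name]
    truth = pd.DataFrame(truth_rows,
                         columns=["order", "scaffold", "orientation",
                                  "t_start", "t_end"])
    return FragmentSim(SequenceSet(presented), anchors, truth, chrom)
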