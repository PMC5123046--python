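"""Readers and writers for the plain-text formats the toolkit consumes.

All in-memory coordinates are 0-based half-open; conversion to each format's
native convention (1-based VCF and AGP, UCSC chain) happens here and only
here.  Plain or gzip-compressed text is supported; BAM/CRAM, tabix and bgzip
management are out of scope.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO

from .liftover import Chain, ChainError

_ALPHABET = frozenset("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")

SV_TYPES = ("INS", "DEL", "INV")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Named nucleotide sequences over {A,C,G,T,N}, uppercase, non-empty."""

    sequences: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalised = {}
        for name, seq in self.sequences.items():
            normalised[name] = _check_sequence(name, seq)
        self.sequences = normalised

    def add(self, name: str, seq: str) -> None:
        if name in self.sequences:
            raise FormatError(f"duplicate sequence name {name!r}")
        self.sequences[name] = _check_sequence(name, seq)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def names(self) -> List[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def items(self):
        return self.sequences.items()


def _check_sequence(name: str, seq: str) -> str:
    if not name:
        raise FormatError("empty sequence name")
    seq = seq.upper()
    if not seq:
        raise FormatError(f"empty sequence for {name!r}")
    bad = set(seq) - _ALPHABET
    if bad:
        raise FormatError(
            f"illegal character(s) {sorted(bad)} in sequence {name!r} "
            "(expected A/C/G/T/N)"
        )
    return seq


def read_fasta(path) -> SequenceSet:
    """Read a FASTA file; sequences are uppercased and validated."""
    seqs: Dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise FormatError(f"duplicate sequence name {rec.id!r}")
            seqs[rec.id] = _check_sequence(rec.id, str(rec.seq))
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return SequenceSet(seqs)


def write_fasta(sequences: SequenceSet, path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """A VCF-style small variant with per-sample genotypes.

    ``pos`` is 0-based; ``genotypes`` maps sample name to a tuple of allele
    indices (0 = ref), with ``None`` marking a missing haploid call.
    """

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    genotypes: Dict[str, Tuple[Optional[int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref:
            raise FormatError(f"empty REF allele at {self.chrom}:{self.pos}")
        if any(a == self.ref for a in self.alts):
            raise FormatError(f"ALT equals REF at {self.chrom}:{self.pos}")
        self.alts = tuple(self.alts)

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    def carried_alleles(self, sample: str) -> List[str]:
        """Allele strings on the called haploids of one sample."""
        alleles = [self.ref, *self.alts]
        return [alleles[i] for i in self.genotypes[sample] if i is not None]


def read_vcf_cohort(path, sample_subset: Optional[Sequence[str]] = None) -> List[VariantRecord]:
    """Read a VCF with GT genotypes into 0-based :class:`VariantRecord` s.

    Multiallelic records are preserved as-is; missing genotypes stay missing
    (they are never imputed — downstream tallies exclude them from called
    haploid denominators).
    """
    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vf.header.samples)
        if sample_subset is not None:
            missing = [s for s in sample_subset if s not in samples]
            if missing:
                raise FormatError(f"{path}: sample(s) not found: {missing}")
            samples = list(sample_subset)
        records: List[VariantRecord] = []
        for rec in vf:
            alts = tuple(a.upper() for a in (rec.alts or ()))
            if not alts:
                continue
            gts = {}
            for s in samples:
                gt = rec.samples[s].get("GT", (None,))
                if gt is None:
                    gt = (None,)
                gts[s] = tuple(gt)
            records.append(
                VariantRecord(rec.chrom, rec.start, rec.ref.upper(), alts, gts)
            )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    contig_lengths: Mapping[str, int],
    path,
    samples: Optional[Sequence[str]] = None,
) -> None:
    """Write records as a minimal VCF 4.2 file with GT genotypes."""
    if samples is None:
        if not records:
            raise FormatError("cannot infer sample names from an empty record list")
        samples = list(records[0].genotypes)
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            gts = []
            for s in samples:
                gt = rec.genotypes.get(s, (None,))
                gts.append("/".join("." if a is None else str(a) for a in gt))
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t{','.join(rec.alts)}\t"
                f".\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

def write_chain(chain: Chain, path) -> None:
    """Write a :class:`Chain` in the UCSC chain dialect (forward strand)."""
    chain.validate()
    with _open_text(path, "wt") as fh:
        cid = 0
        for chrom in chain.blocks:
            blocks = chain.blocks[chrom]
            if not blocks:
                continue
            cid += 1
            score = sum(s1 - s0 for s0, s1, _, _ in blocks)
            s_lo, s_hi = blocks[0][0], blocks[-1][1]
            t_lo, t_hi = blocks[0][2], blocks[-1][3]
            fh.write(
                f"chain {score} {chrom} {chain.source_sizes[chrom]} + {s_lo} {s_hi} "
                f"{chrom} {chain.target_sizes[chrom]} + {t_lo} {t_hi} {cid}\n"
            )
            for k, (s0, s1, t0, t1) in enumerate(blocks):
                size = s1 - s0
                if k + 1 < len(blocks):
                    ns0, _, nt0, _ = blocks[k + 1]
                    fh.write(f"{size} {ns0 - s1} {nt0 - t1}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


def read_chain(path) -> Chain:
    """Read a UCSC chain file produced by :func:`write_chain`."""
    chain = Chain()
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        parts = line.split()
        if parts[0] != "chain" or len(parts) != 13:
            raise FormatError(f"malformed chain header: {line!r}")
        (_, _, s_name, s_size, s_strand, s_start, s_end,
         t_name, t_size, t_strand, t_start, t_end, _) = parts
        if s_strand != "+" or t_strand != "+":
            raise FormatError("only forward-strand chains are supported")
        if s_name != t_name:
            raise FormatError("only same-chromosome chains are supported")
        s_pos, t_pos = int(s_start), int(t_start)
        blocks: List[Tuple[int, int, int, int]] = []
        while i < len(lines) and lines[i].strip():
            fields = lines[i].split()
            i += 1
            size = int(fields[0])
            blocks.append((s_pos, s_pos + size, t_pos, t_pos + size))
            if len(fields) == 3:
                dt, dq = int(fields[1]), int(fields[2])
                if dt < 0 or dq < 0:
                    raise FormatError(f"negative gap in chain for {s_name}")
                s_pos += size + dt
                t_pos += size + dq
            elif len(fields) == 1:
                s_pos += size
                t_pos += size
                break
            else:
                raise FormatError(f"malformed chain data line: {lines[i - 1]!r}")
        if s_pos != int(s_end) or t_pos != int(t_end):
            raise FormatError(f"chain block sum disagrees with header for {s_name}")
        chain.blocks[s_name] = blocks
        chain.source_sizes[s_name] = int(s_size)
        chain.target_sizes[s_name] = int(t_size)
    try:
        chain.validate()
    except ChainError as exc:
        raise FormatError(str(exc)) from exc
    return chain


# ---------------------------------------------------------------------------
# Structural variants (TSV interchange)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVRecord:
    """A typed structural variant on baseline-reference coordinates.

    Insertions carry ``end == start`` (a breakpoint) and their inserted
    length in ``sv_length``; deletions and inversions span ``[start, end)``
    with ``sv_length == end - start``.
    """

    chrom: str
    start: int
    end: int
    sv_type: str
    sv_length: int
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise FormatError(f"unknown SV type {self.sv_type!r}")
        if self.start > self.end:
            raise FormatError(f"start > end for SV at {self.chrom}:{self.start}")
        if self.sv_type == "INS":
            if self.end != self.start or self.sv_length < 1:
                raise FormatError(
                    f"INS at {self.chrom}:{self.start} must have end == start and length >= 1"
                )
        else:
            if self.sv_length != self.end - self.start or self.sv_length < 1:
                raise FormatError(
                    f"{self.sv_type} at {self.chrom}:{self.start} must have "
                    "length == end - start >= 1"
                )


SV_COLUMNS = ["chrom", "start", "end", "type", "length", "label"]


def write_sv_tsv(svs: Sequence[SVRecord], path) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.sv_type, s.sv_length, s.source_label) for s in svs],
        columns=SV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_sv_tsv(path, label: Optional[str] = None) -> List[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "label": str})
    missing = [c for c in SV_COLUMNS if c not in df.columns and c != "label"]
    if missing:
        raise FormatError(f"{path}: missing SV columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        lab = label if label is not None else str(getattr(row, "label", ""))
        out.append(
            SVRecord(str(row.chrom), int(row.start), int(row.end), str(row.type),
                     int(row.length), lab)
        )
    return out


# ---------------------------------------------------------------------------
# Alignment anchors (TSV or PAF)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """One scaffold-on-reference alignment block used for chromosome building."""

    scaffold: str
    chrom: str
    s_start: int
    s_end: int
    t_start: int
    t_end: int
    strand: str
    quality: int


ANCHOR_COLUMNS = ["scaffold", "chrom", "s_start", "s_end", "t_start", "t_end",
                  "strand", "quality"]


def write_anchors(anchors: Sequence[Anchor], path) -> None:
    df = pd.DataFrame([a.__dict__ for a in anchors], columns=ANCHOR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_anchors(path) -> List[Anchor]:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "chrom": str, "strand": str})
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing anchor columns {missing}")
    return [
        Anchor(str(r.scaffold), str(r.chrom), int(r.s_start), int(r.s_end),
               int(r.t_start), int(r.t_end), str(r.strand), int(r.quality))
        for r in df.itertuples(index=False)
    ]


def read_anchors_paf(path) -> List[Anchor]:
    """Read minimap2-style PAF lines into anchors (mapq column 12)."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"PAF line with fewer than 12 columns: {line!r}")
            out.append(
                Anchor(f[0], f[5], int(f[2]), int(f[3]), int(f[7]), int(f[8]),
                       f[4], int(f[11]))
            )
    return out


# ---------------------------------------------------------------------------
# S/P read-support counts
# ---------------------------------------------------------------------------

def read_sp_counts(path) -> pd.DataFrame:
    """Read per-region single-end/paired read counts (columns: region, single, paired)."""
    df = pd.read_csv(path, sep="\t", dtype={"region": str})
    for col in ("region", "single", "paired"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if (df["single"] < 0).any() or (df["paired"] < 0).any():
        raise FormatError(f"{path}: negative read counts")
    return df


# ---------------------------------------------------------------------------
# AGP 2.0
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AGPRow:
    """One AGP 2.0 line (0-based half-open internally; 1-based on disk)."""

    obj: str
    beg: int
    end: int
    part: int
    comp_type: str  # 'W' scaffold component, 'N' gap
    comp_id: str = ""
    comp_beg: int = 0
    comp_end: int = 0
    orientation: str = "+"
    gap_length: int = 0
    gap_type: str = ""
    linkage: str = "no"


def write_agp(rows: Sequence[AGPRow], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##agp-version\t2.0\n")
        for r in rows:
            if r.comp_type == "W":
                fh.write(
                    f"{r.obj}\t{r.beg + 1}\t{r.end}\t{r.part}\tW\t{r.comp_id}\t"
                    f"{r.comp_beg + 1}\t{r.comp_end}\t{r.orientation}\n"
                )
            else:
                fh.write(
                    f"{r.obj}\t{r.beg + 1}\t{r.end}\t{r.part}\tN\t{r.gap_length}\t"
                    f"{r.gap_type}\t{r.linkage}\tna\n"
                )


def read_agp(path) -> List[AGPRow]:
    rows: List[AGPRow] = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"AGP line with fewer than 9 columns: {line!r}")
            obj, beg, end, part, ctype = f[0], int(f[1]) - 1, int(f[2]), int(f[3]), f[4]
            if ctype == "W":
                rows.append(AGPRow(obj, beg, end, part, "W", f[5], int(f[6]) - 1,
                                   int(f[7]), f[8]))
            elif ctype in ("N", "U"):
                rows.append(AGPRow(obj, beg, end, part, "N",
                                   gap_length=int(f[5]), gap_type=f[6], linkage=f[7]))
            else:
                raise FormatError(f"unsupported AGP component type {ctype!r}")
    return rows


# ---------------------------------------------------------------------------
# BED-like helpers
# ---------------------------------------------------------------------------

def read_bed_intervals(path) -> Dict[str, List[Tuple[int, int]]]:
    """Read (chrom, start, end) intervals from a BED-like file."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


def write_bed_intervals(intervals: Mapping[str, Sequence[Tuple[int, int]]], path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, ivs in intervals.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")
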