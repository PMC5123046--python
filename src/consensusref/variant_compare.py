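"""Per-individual variant-set comparison across references.

Implements the comparison semantics used when the same individual's reads
are called against two references: restriction to mutually alignable
regions, zygosity-by-class count tables, reference-specific variant
decomposition via lift-over with allele re-expression, and sharedness
spectra across individuals.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple

from .consensus import normalize_variant
from .io_formats import SequenceSet, VariantRecord
from .liftover import Chain, LiftStatus, lift_variant, map_interval

logger = logging.getLogger(__name__)

HOM = "HOM"
HET = "HET"
SNV = "SNV"
INDEL = "INDEL"


@dataclass(frozen=True)
class GenotypedCall:
    """One non-reference genotype call of one individual against one reference."""

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    gt: Tuple[int, ...]
    zygosity: str
    var_class: str
    individual: str
    reference_label: str

    @property
    def record(self) -> VariantRecord:
        return VariantRecord(self.chrom, self.pos, self.ref, self.alts,
                             {self.individual: self.gt})


def calls_from_records(
    records: Sequence[VariantRecord],
    individual: str,
    reference_label: str,
) -> List[GenotypedCall]:
    """Extract one individual's non-reference calls, classified by zygosity/class.

    Zygosity comes from GT alone (0/1 -> HET, 1/1 -> HOM); genotypes with a
    missing haploid are excluded and logged; hom-reference genotypes yield
    no call.  A call is an SNV only when every carried allele is a single
    base replacing a single base.
    """
    out: List[GenotypedCall] = []
    for rec in records:
        gt = rec.genotypes.get(individual)
        if gt is None:
            continue
        if any(a is None for a in gt):
            if any(a is not None for a in gt):
                logger.debug("excluding half-missing genotype at %s:%d", rec.chrom, rec.pos)
            continue
        carried = [a for a in gt if a > 0]
        if not carried:
            continue
        zyg = HOM if len(set(gt)) == 1 else HET
        alleles = [rec.ref, *rec.alts]
        is_snv = len(rec.ref) == 1 and all(len(alleles[a]) == 1 for a in carried)
        out.append(
            GenotypedCall(rec.chrom, rec.pos, rec.ref, rec.alts, tuple(gt),
                          zyg, SNV if is_snv else INDEL, individual, reference_label)
        )
    return out


def restrict_to_shared_regions(
    calls: Sequence[GenotypedCall],
    chains: Sequence[Chain],
    mode: str = "span",
) -> List[GenotypedCall]:
    """Keep only calls whose positions are mappable through every chain.

    ``mode='span'`` (default) requires the whole reference span of the call
    to map; ``mode='pos'`` requires only the start position.
    """
    if mode not in ("span", "pos"):
        raise ValueError(f"mode must be 'span' or 'pos', got {mode!r}")
    if not chains:
        raise ValueError("at least one chain is required")
    kept = []
    for call in calls:
        ok = True
        for chain in chains:
            if call.chrom not in chain.blocks:
                ok = False
                break
            span = (call.pos, call.pos + (len(call.ref) if mode == "span" else 1))
            mapped = map_interval(chain, call.chrom, *span)
            if sum(e - s for s, e in mapped) != span[1] - span[0]:
                ok = False
                break
        if ok:
            kept.append(call)
    return kept


_TABLE_KEYS = [(HOM, SNV), (HOM, INDEL), (HET, SNV), (HET, INDEL)]


def count_by_zygosity_and_class(
    calls: Sequence[GenotypedCall],
) -> Dict[str, Dict[Tuple[str, str], int]]:
    """Per-individual 2x2 table of call counts by zygosity and variant class."""
    out: Dict[str, Dict[Tuple[str, str], int]] = {}
    for call in calls:
        table = out.setdefault(call.individual, {k: 0 for k in _TABLE_KEYS})
        table[(call.zygosity, call.var_class)] += 1
    return out


def _call_key(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    gt: Sequence[int],
    seq: str,
) -> Optional[Tuple]:
    """Canonical key for 'the same variant with the same carried alleles'.

    Each carried haploid allele is normalised (trimmed, left-aligned)
    against the reference it is expressed on; hom calls carry the allele
    twice, so zygosity participates in identity.  Returns ``None`` for
    hom-reference genotypes (no variant).
    """
    alleles = [ref, *alts]
    carried = []
    for a in gt:
        if a > 0:
            carried.append(normalize_variant(seq, pos, ref, alleles[a]))
    if not carried:
        return None
    return (chrom, tuple(sorted(carried)))


def reference_specific_variants(
    calls_a: Sequence[GenotypedCall],
    calls_b: Sequence[GenotypedCall],
    chain: Chain,
    target_sequences: SequenceSet,
) -> Tuple[List[GenotypedCall], List[GenotypedCall], List[GenotypedCall]]:
    """Split two call sets of one individual into (shared, A-only, B-only).

    A-calls are lifted onto B's reference through ``chain``; a variant is
    shared when the lift succeeds and position plus normalised
    genotype-carried alleles match a B-call.  Lifts whose re-expressed
    genotype is hom-reference (the consensus absorbed the allele) are
    A-only absences, as are unmappable calls.
    """
    b_keys: Counter = Counter()
    b_by_key: Dict[Tuple, List[GenotypedCall]] = {}
    for call in calls_b:
        key = _call_key(call.chrom, call.pos, call.ref, call.alts, call.gt,
                        target_sequences[call.chrom])
        if key is not None:
            b_keys[key] += 1
            b_by_key.setdefault(key, []).append(call)

    shared: List[GenotypedCall] = []
    a_only: List[GenotypedCall] = []
    for call in calls_a:
        res = lift_variant(chain, target_sequences, call.record)
        if res.status is LiftStatus.UNMAPPED:
            a_only.append(call)
            continue
        lifted = res.variant
        gt = lifted.genotypes[call.individual]
        key = _call_key(lifted.chrom, lifted.pos, lifted.ref, lifted.alts, gt,
                        target_sequences[lifted.chrom])
        if key is not None and b_keys.get(key, 0) > 0:
            b_keys[key] -= 1
            shared.append(call)
        else:
            a_only.append(call)

    b_only: List[GenotypedCall] = []
    for key, calls in b_by_key.items():
        b_only.extend(calls[: b_keys[key]])
    return shared, a_only, b_only


def sharedness_spectrum(
    per_individual_sets: Mapping[str, Iterable[Hashable]],
) -> Dict[int, int]:
    """Histogram of variants over the number of individuals carrying them.

    The weighted sum ``sum(bin * count)`` equals the total number of
    variant-individual incidences.
    """
    if len(per_individual_sets) < 2:
        raise ValueError("need at least two individuals for a sharedness spectrum")
    incidence: Counter = Counter()
    for _, keys in per_individual_sets.items():
        for key in set(keys):
            incidence[key] += 1
    spectrum: Dict[int, int] = {}
    for n in incidence.values():
        spectrum[n] = spectrum.get(n, 0) + 1
    return dict(sorted(spectrum.items()))


def annotate_known(
    calls: Sequence[GenotypedCall],
    known_sites: Iterable[Tuple[str, int, str, str]],
) -> List[bool]:
    """Flag calls whose (chrom, pos, ref, alt) appears in a known-sites set.

    A call counts as known when every carried alt allele is present in the
    lookup (a local stand-in for a dbSNP membership query; no network).
    """
    known = set(known_sites)
    flags = []
    for call in calls:
        alleles = [call.ref, *call.alts]
        carried = {alleles[a] for a in call.gt if a > 0}
        flags.append(all((call.chrom, call.pos, call.ref, alt) in known for alt in carried))
    return flags
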