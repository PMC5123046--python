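"""Population consensus reference construction.

Given a baseline reference and a cohort VCF, this module tallies allele
support over called haploids, selects substitutions — the cohort-major
allele at SNV sites, and indels carried by strictly more than half of the
chromosome's haploid capacity (the "over 40 of 80 haploids" rule, with
sex-chromosome capacities of 30 female-X and 25 male-Y haploids for a
25-male/15-female cohort of 40) — applies them to the reference, and emits
the consensus sequence together with a lift-over chain describing the
induced coordinate changes.

Conventions, chosen once and surfaced in the edit report:

* SNV plurality is over *called* haploids (missing genotypes shrink the
  denominator); a tie, including ref-vs-alt 50/50, keeps the reference
  because a tie has no unique most-frequent allele.
* The indel threshold is an absolute count against chromosome haploid
  *capacity*, not the called denominator.
* Edits are selected SNVs first, then indels; an indel whose reference span
  overlaps a previously accepted edit is dropped and logged.
* Indels are left-aligned and parsimony-trimmed before tallying so that
  identical events aggregate across representations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .io_formats import SequenceSet, VariantRecord
from .liftover import Chain

logger = logging.getLogger(__name__)

SNV = "SNV"
INDEL = "INDEL"


class EditError(ValueError):
    """Raised when an edit script is inconsistent with the reference."""


class PloidyError(ValueError):
    """Raised when a genotype's arity conflicts with the ploidy scheme."""


# ---------------------------------------------------------------------------
# Ploidy
# ---------------------------------------------------------------------------

@dataclass
class PloidyScheme:
    """Per-chromosome haploid capacity derived from cohort sex composition.

    Autosomes carry two haploids per sample.  Following the source scheme,
    the X chromosome counts only female samples (two haploids each) and the
    Y chromosome only male samples (one haploid each); pseudo-autosomal
    regions receive no special treatment.
    """

    sexes: Dict[str, str]  # sample -> 'M' | 'F'
    x_chrom: str = "chrX"
    y_chrom: str = "chrY"

    def __post_init__(self) -> None:
        bad = {s: v for s, v in self.sexes.items() if v not in ("M", "F")}
        if bad:
            raise ValueError(f"sex must be 'M' or 'F': {bad}")

    @classmethod
    def all_diploid(cls, samples: Iterable[str]) -> "PloidyScheme":
        """Autosome-only convenience: every sample counts two haploids."""
        return cls({s: "F" for s in samples}, x_chrom="__x__", y_chrom="__y__")

    @property
    def samples(self) -> List[str]:
        return list(self.sexes)

    def arity(self, chrom: str, sample: str) -> int:
        sex = self.sexes[sample]
        if chrom == self.x_chrom:
            return 2 if sex == "F" else 0
        if chrom == self.y_chrom:
            return 1 if sex == "M" else 0
        return 2

    def capacity(self, chrom: str) -> int:
        cap = sum(self.arity(chrom, s) for s in self.sexes)
        if cap < 1:
            raise PloidyError(f"zero haploid capacity for {chrom!r}")
        return cap


@dataclass
class SubstitutionPolicy:
    """Selection thresholds; the defaults generalise the source rules.

    ``indel_fraction=0.5`` means an indel is substituted when its haploid
    support strictly exceeds half of the chromosome's haploid capacity
    (41 of 80 qualifies, 40 does not; 16 of 30 qualifies on an X counted
    from 15 females).
    """

    indel_fraction: float = 0.5


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize_variant(seq: str, pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Parsimony-trim and left-align one allele pair against ``seq``.

    Returns ``(pos, ref, alt)`` with the shared prefix/suffix removed; pure
    insertions end with ``ref == ""`` and deletions with ``alt == ""``, both
    shifted as far left as the sequence context allows.
    """
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref and not alt:  # deletion: shift left through repeat context
        while pos > 0 and seq[pos - 1] == ref[-1]:
            ref = seq[pos - 1] + ref[:-1]
            pos -= 1
    elif alt and not ref:  # insertion
        while pos > 0 and seq[pos - 1] == alt[-1]:
            alt = seq[pos - 1] + alt[:-1]
            pos -= 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------

@dataclass
class CohortSiteTally:
    """Haploid allele counts at one site (SNV) or for one indel event.

    For ``kind == 'SNV'`` the ``counts`` map single bases (reference
    included) to haploid counts and ``alt`` is ``None``.  For
    ``kind == 'INDEL'`` the tally describes one normalised event: ``ref`` is
    the deleted span (may be empty), ``alt`` the replacement, and ``counts``
    holds the supporting and non-supporting called haploids.  In both cases
    ``sum(counts) == called <= total`` where ``total`` is the chromosome's
    haploid capacity.
    """

    chrom: str
    pos: int
    ref: str
    kind: str
    counts: Dict[str, int]
    called: int
    total: int
    alt: Optional[str] = None

    @property
    def support(self) -> int:
        """Supporting haploids of the event allele (indel tallies only)."""
        if self.alt is None:
            raise ValueError("support is defined for indel tallies only")
        return self.counts[self.alt]


def _decompose(rec: VariantRecord, reference: Optional[SequenceSet]):
    """Split a (possibly multiallelic) record into atomic allele events.

    Returns ``(snv_positions, base_of, indel_events)`` where ``base_of[j]``
    maps each SNV position to the base carried by allele index ``j`` (absent
    when allele ``j`` does not determine a base there) and ``indel_events[j]``
    lists normalised ``(pos, ref, alt)`` events for allele ``j``.
    """
    seq = reference[rec.chrom] if reference is not None and rec.chrom in reference else None

    snv_positions: set = set()
    per_alt_aligned: Dict[int, Tuple[int, str, str]] = {}
    indel_events: Dict[int, List[Tuple[int, str, str]]] = {}
    for j, alt in enumerate(rec.alts, start=1):
        ref, a, pos = rec.ref, alt, rec.pos
        while ref and a and ref[-1] == a[-1] and len(ref) > 1 and len(a) > 1:
            ref, a = ref[:-1], a[:-1]
        while ref and a and ref[0] == a[0] and len(ref) > 1 and len(a) > 1:
            ref, a = ref[1:], a[1:]
            pos += 1
        if len(ref) == len(a):
            per_alt_aligned[j] = (pos, ref, a)
            for k in range(len(ref)):
                if ref[k] != a[k]:
                    snv_positions.add(pos + k)
        else:
            if seq is not None:
                npos, nref, nalt = normalize_variant(seq, pos, ref, a)
            else:  # no context: trim only, no left-alignment
                npos, nref, nalt = pos, ref, a
                while nref and nalt and nref[-1] == nalt[-1]:
                    nref, nalt = nref[:-1], nalt[:-1]
                while nref and nalt and nref[0] == nalt[0]:
                    nref, nalt = nref[1:], nalt[1:]
                    npos += 1
            indel_events.setdefault(j, []).append((npos, nref, nalt))

    def base_of(j: int, q: int) -> Optional[str]:
        if j == 0:
            return rec.ref[q - rec.pos]
        if j in indel_events:
            return None  # length-changing allele determines no base here
        pos, ref, a = per_alt_aligned[j]
        if pos <= q < pos + len(ref):
            return a[q - pos]
        return rec.ref[q - rec.pos]

    return sorted(snv_positions), base_of, indel_events


def tally_alleles(
    records: Sequence[VariantRecord],
    scheme: PloidyScheme,
    reference: Optional[SequenceSet] = None,
) -> List[CohortSiteTally]:
    """Tally per-site haploid allele support over the cohort.

    Uncalled haploids are excluded from the counts but retained in the
    capacity denominator ``total``.  Passing the baseline ``reference``
    enables left-alignment of indel events so equivalent representations
    aggregate.
    """
    snv: Dict[Tuple[str, int], Dict] = {}
    indel: Dict[Tuple[str, int, str, str], Dict] = {}

    for rec in records:
        snv_positions, base_of, indel_events = _decompose(rec, reference)
        sample_alleles: List[Tuple[str, Tuple[Optional[int], ...]]] = []
        for sample, gt in rec.genotypes.items():
            arity = scheme.arity(rec.chrom, sample)
            called = [a for a in gt if a is not None]
            if not called:
                continue
            if arity == 0:
                raise PloidyError(
                    f"sample {sample!r} has a genotype on {rec.chrom} but zero "
                    "haploid capacity there"
                )
            if len(gt) != arity:
                raise PloidyError(
                    f"sample {sample!r} at {rec.chrom}:{rec.pos}: genotype arity "
                    f"{len(gt)} conflicts with ploidy {arity}"
                )
            sample_alleles.append((sample, gt))

        for q in snv_positions:
            key = (rec.chrom, q)
            entry = snv.setdefault(
                key, {"ref": rec.ref[q - rec.pos], "counts": {}, "called": 0}
            )
            for _, gt in sample_alleles:
                for a in gt:
                    if a is None:
                        continue
                    base = base_of(a, q)
                    if base is None:
                        continue
                    entry["counts"][base] = entry["counts"].get(base, 0) + 1
                    entry["called"] += 1

        if indel_events:
            n_called = sum(
                1 for _, gt in sample_alleles for a in gt if a is not None
            )
            for j, events in indel_events.items():
                for (p, r, a) in events:
                    key = (rec.chrom, p, r, a)
                    support = sum(
                        1 for _, gt in sample_alleles for al in gt if al == j
                    )
                    entry = indel.setdefault(key, {"support": 0, "called": 0})
                    entry["support"] += support
                    entry["called"] = max(entry["called"], n_called)

    tallies: List[CohortSiteTally] = []
    for (chrom, pos), entry in snv.items():
        counts = dict(entry["counts"])
        counts.setdefault(entry["ref"], 0)
        tallies.append(
            CohortSiteTally(
                chrom, pos, entry["ref"], SNV, counts,
                called=entry["called"], total=scheme.capacity(chrom),
            )
        )
    for (chrom, pos, ref, alt), entry in indel.items():
        support, called = entry["support"], entry["called"]
        counts = {alt: support}
        counts[ref] = counts.get(ref, 0) + (called - support)
        tallies.append(
            CohortSiteTally(
                chrom, pos, ref, INDEL, counts,
                called=called, total=scheme.capacity(chrom), alt=alt,
            )
        )
    tallies.sort(key=lambda t: (t.chrom, t.pos, t.kind, t.alt or ""))
    return tallies


# ---------------------------------------------------------------------------
# Edit selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Edit:
    """One reference edit: replace ``ref`` (possibly empty) at ``pos`` by ``alt``."""

    pos: int
    ref: str
    alt: str
    kind: str

    @property
    def span(self) -> Tuple[int, int]:
        return self.pos, self.pos + len(self.ref)


@dataclass
class EditScript:
    """Ordered, non-overlapping edits per chromosome."""

    edits: Dict[str, List[Edit]] = field(default_factory=dict)

    def validate(self, reference: SequenceSet) -> None:
        for chrom, edits in self.edits.items():
            seq = reference[chrom]
            prev_end = -1
            prev_zero_pos = -1
            for e in edits:
                s, t = e.span
                if s < prev_end or (s == t and s == prev_zero_pos):
                    raise EditError(f"{chrom}: overlapping edits near position {s}")
                if t > len(seq):
                    raise EditError(f"{chrom}: edit at {s} exceeds sequence length")
                if seq[s:t] != e.ref:
                    raise EditError(
                        f"{chrom}:{s}: edit ref {e.ref!r} does not match reference "
                        f"{seq[s:t]!r}"
                    )
                prev_end = max(prev_end, t)
                prev_zero_pos = s if s == t else prev_zero_pos

    def total_edits(self) -> int:
        return sum(len(v) for v in self.edits.values())


def select_snv_substitutions(tallies: Sequence[CohortSiteTally]) -> Dict[str, List[Edit]]:
    """Emit an edit wherever a unique cohort-major base differs from the reference.

    Ties (including exact 50/50) keep the reference: a tie has no unique
    most-frequent allele.
    """
    out: Dict[str, List[Edit]] = {}
    for t in tallies:
        if t.kind != SNV or t.called == 0:
            continue
        best = max(t.counts.values())
        winners = [a for a, c in t.counts.items() if c == best]
        if len(winners) == 1 and winners[0] != t.ref:
            out.setdefault(t.chrom, []).append(Edit(t.pos, t.ref, winners[0], SNV))
    for edits in out.values():
        edits.sort()
    return out


def select_indel_substitutions(
    tallies: Sequence[CohortSiteTally],
    policy: Optional[SubstitutionPolicy] = None,
) -> Dict[str, List[Edit]]:
    """Emit an edit for indels supported by more than ``indel_fraction`` of capacity.

    The comparison is strict: at the default fraction 0.5 an autosomal indel
    needs at least 41 of 80 haploids.
    """
    policy = policy or SubstitutionPolicy()
    out: Dict[str, List[Edit]] = {}
    for t in tallies:
        if t.kind != INDEL:
            continue
        if t.support > policy.indel_fraction * t.total:
            out.setdefault(t.chrom, []).append(Edit(t.pos, t.ref, t.alt, INDEL))
    for edits in out.values():
        edits.sort()
    return out


def _spans_conflict(a0: int, a1: int, b0: int, b1: int) -> bool:
    """Overlap test with zero-length (insertion) spans handled explicitly."""
    if a0 == a1 and b0 == b1:
        return a0 == b0
    if a0 == a1:
        return b0 < a0 < b1
    if b0 == b1:
        return a0 < b0 < a1
    return a0 < b1 and b0 < a1


def resolve_conflicts(
    snv_edits: Mapping[str, Sequence[Edit]],
    indel_edits: Mapping[str, Sequence[Edit]],
) -> Tuple[EditScript, List[Tuple[str, Edit, str]]]:
    """Merge SNV and indel edits with SNVs-first precedence.

    Any indel whose reference span overlaps a previously accepted edit is
    dropped and reported, keeping the script valid and the decision
    auditable.
    """
    script: Dict[str, List[Edit]] = {}
    dropped: List[Tuple[str, Edit, str]] = []
    chroms = set(snv_edits) | set(indel_edits)
    for chrom in sorted(chroms):
        accepted: List[Edit] = sorted(snv_edits.get(chrom, ()))
        spans = [e.span for e in accepted]
        for e in sorted(indel_edits.get(chrom, ())):
            s, t = e.span
            clash = any(_spans_conflict(s, t, b0, b1) for b0, b1 in spans)
            if clash:
                dropped.append((chrom, e, "overlaps a previously accepted edit"))
                logger.warning("dropping indel edit %s:%d (%s)", chrom, e.pos, e.ref)
            else:
                accepted.append(e)
                spans.append((s, t))
        accepted.sort(key=lambda e: (e.pos, e.pos + len(e.ref)))
        if accepted:
            script[chrom] = accepted
    return EditScript(script), dropped


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def apply_edits(reference: SequenceSet, script: EditScript) -> Tuple[SequenceSet, Chain]:
    """Apply an edit script left-to-right and derive the lift-over chain.

    Same-length (SNV) edits do not interrupt chain blocks; length-changing
    edits close the current block and open source/target gaps.  Chain blocks
    therefore exactly describe the unedited (and SNV-substituted) stretches.
    """
    script.validate(reference)
    out_seqs: Dict[str, str] = {}
    chain = Chain()
    for chrom, seq in reference.items():
        edits = script.edits.get(chrom, [])
        parts: List[str] = []
        blocks: List[Tuple[int, int, int, int]] = []
        last = 0
        bs = bt = t = 0
        for e in edits:
            s, span_end = e.span
            seg = seq[last:s]
            parts.append(seg)
            t += len(seg)
            if len(e.ref) == len(e.alt):
                parts.append(e.alt)
                t += len(e.alt)
            else:
                if s > bs:
                    blocks.append((bs, s, bt, bt + (s - bs)))
                parts.append(e.alt)
                t += len(e.alt)
                bs, bt = span_end, t
            last = span_end
        tail = seq[last:]
        parts.append(tail)
        t += len(tail)
        if len(seq) > bs:
            blocks.append((bs, len(seq), bt, bt + (len(seq) - bs)))
        cons = "".join(parts)
        out_seqs[chrom] = cons
        chain.blocks[chrom] = blocks
        chain.source_sizes[chrom] = len(seq)
        chain.target_sizes[chrom] = len(cons)
    chain.validate()
    return SequenceSet(out_seqs), chain


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    consensus: SequenceSet
    chain: Chain
    script: EditScript
    report: pd.DataFrame  # every substitution with its haploid support
    dropped: List[Tuple[str, Edit, str]]


def build_consensus(
    reference: SequenceSet,
    cohort: Sequence[VariantRecord],
    scheme: PloidyScheme,
    policy: Optional[SubstitutionPolicy] = None,
) -> ConsensusResult:
    """Tally, select, reconcile and apply cohort substitutions.

    The report lists every candidate edit with its haploid support and
    whether it was applied or dropped, so threshold and conflict decisions
    stay auditable.
    """
    policy = policy or SubstitutionPolicy()
    tallies = tally_alleles(cohort, scheme, reference)
    snv_edits = select_snv_substitutions(tallies)
    indel_edits = select_indel_substitutions(tallies, policy)
    script, dropped = resolve_conflicts(snv_edits, indel_edits)
    consensus, chain = apply_edits(reference, script)

    support_lookup: Dict[Tuple[str, int, str, Optional[str]], CohortSiteTally] = {}
    for t in tallies:
        support_lookup[(t.chrom, t.pos, t.kind, t.alt)] = t
    dropped_set = {(chrom, e) for chrom, e, _ in dropped}
    rows = []
    for chrom, edits in script.edits.items():
        for e in edits:
            t = support_lookup.get((chrom, e.pos, e.kind, e.alt if e.kind == INDEL else None))
            support = t.counts.get(e.alt, 0) if t is not None else 0
            rows.append((chrom, e.pos, e.kind, e.ref, e.alt, support,
                         t.called if t else 0, t.total if t else 0, "applied", ""))
    for chrom, e, reason in dropped:
        t = support_lookup.get((chrom, e.pos, e.kind, e.alt))
        rows.append((chrom, e.pos, e.kind, e.ref, e.alt,
                     t.counts.get(e.alt, 0) if t else 0,
                     t.called if t else 0, t.total if t else 0, "dropped", reason))
    report = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "kind", "ref", "alt", "support", "called",
                 "capacity", "status", "reason"],
    ).sort_values(["chrom", "pos", "kind"], kind="stable").reset_index(drop=True)
    return ConsensusResult(consensus, chain, script, report, dropped)
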