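"""Chain-based coordinate and variant mapping between two references.

A :class:`Chain` describes a same-chromosome, forward-strand alignment
between a *source* assembly (e.g. the single-donor baseline) and a *target*
assembly (e.g. the population consensus) as ordered, non-overlapping blocks.
Within a block coordinates map affinely; positions falling in source-only
gaps (bases deleted from the target) are unmappable.  Substitution-induced
chains cannot rearrange sequence, so inversions/translocations are out of
scope by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

#: (source_start, source_end, target_start, target_end), 0-based half-open.
Block = Tuple[int, int, int, int]

FORWARD = "forward"
BACKWARD = "backward"


class ChainError(ValueError):
    """Raised when chain blocks violate the monotonicity/size invariants."""


@dataclass
class Chain:
    """Per-chromosome aligned blocks plus the sequence sizes on both sides."""

    blocks: Dict[str, List[Block]] = field(default_factory=dict)
    source_sizes: Dict[str, int] = field(default_factory=dict)
    target_sizes: Dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for chrom, blocks in self.blocks.items():
            if chrom not in self.source_sizes or chrom not in self.target_sizes:
                raise ChainError(f"no sequence sizes recorded for {chrom!r}")
            ssize = self.source_sizes[chrom]
            tsize = self.target_sizes[chrom]
            prev_s = prev_t = -1
            for s0, s1, t0, t1 in blocks:
                if s1 - s0 != t1 - t0:
                    raise ChainError(f"{chrom}: block {s0}-{s1} vs {t0}-{t1} size mismatch")
                if s1 <= s0:
                    raise ChainError(f"{chrom}: empty or inverted block at {s0}")
                if s0 <= prev_s or t0 <= prev_t:
                    raise ChainError(f"{chrom}: blocks not strictly increasing at {s0}")
                if s0 < 0 or s1 > ssize or t0 < 0 or t1 > tsize:
                    raise ChainError(f"{chrom}: block {s0}-{s1} outside sequence bounds")
                prev_s, prev_t = s1 - 1, t1 - 1

    @classmethod
    def identity(cls, lengths: Mapping[str, int]) -> "Chain":
        """Identity chain mapping every position of each sequence to itself."""
        return cls(
            blocks={c: [(0, n, 0, n)] for c, n in lengths.items() if n > 0},
            source_sizes=dict(lengths),
            target_sizes=dict(lengths),
        )

    def inverted(self) -> "Chain":
        """Swap source and target roles (maps consensus back to baseline)."""
        return Chain(
            blocks={
                c: [(t0, t1, s0, s1) for s0, s1, t0, t1 in blocks]
                for c, blocks in self.blocks.items()
            },
            source_sizes=dict(self.target_sizes),
            target_sizes=dict(self.source_sizes),
        )

    def source_gap_length(self, chrom: str) -> int:
        """Total number of source bases with no image (deleted spans)."""
        blocks = self.blocks[chrom]
        aligned = sum(s1 - s0 for s0, s1, _, _ in blocks)
        return self.source_sizes[chrom] - aligned

    def _index(self, chrom: str, direction: str):
        cache = self.__dict__.setdefault("_idx_cache", {})
        key = (chrom, direction)
        if key not in cache:
            blocks = self.blocks[chrom]
            if direction == FORWARD:
                starts = np.array([b[0] for b in blocks], dtype=np.int64)
                ends = np.array([b[1] for b in blocks], dtype=np.int64)
                other = np.array([b[2] for b in blocks], dtype=np.int64)
            else:
                starts = np.array([b[2] for b in blocks], dtype=np.int64)
                ends = np.array([b[3] for b in blocks], dtype=np.int64)
                other = np.array([b[0] for b in blocks], dtype=np.int64)
            cache[key] = (starts, ends, other)
        return cache[key]


def _check_direction(direction: str) -> None:
    if direction not in (FORWARD, BACKWARD):
        raise ValueError(f"direction must be {FORWARD!r} or {BACKWARD!r}, got {direction!r}")


def map_position(chain: Chain, chrom: str, pos: int, direction: str = FORWARD) -> Optional[int]:
    """Map a single position; return ``None`` when it falls in a gap.

    Positions inside a block map affinely.  A source position inside a span
    deleted from the target (or, backwards, inside an inserted run) has no
    image and returns ``None``.
    """
    _check_direction(direction)
    if chrom not in chain.blocks:
        raise KeyError(f"chromosome {chrom!r} not in chain")
    starts, ends, other = chain._index(chrom, direction)
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i < 0 or pos >= ends[i]:
        return None
    return int(other[i] + (pos - starts[i]))


def map_positions(
    chain: Chain, chrom: str, positions: np.ndarray, direction: str = FORWARD
) -> np.ndarray:
    """Vectorised :func:`map_position`; unmapped positions become -1."""
    _check_direction(direction)
    if chrom not in chain.blocks:
        raise KeyError(f"chromosome {chrom!r} not in chain")
    starts, ends, other = chain._index(chrom, direction)
    pos = np.asarray(positions, dtype=np.int64)
    i = np.searchsorted(starts, pos, side="right") - 1
    valid = i >= 0
    i_safe = np.where(valid, i, 0)
    inside = valid & (pos < ends[i_safe])
    out = np.where(inside, other[i_safe] + (pos - starts[i_safe]), -1)
    return out.astype(np.int64)


def map_interval(
    chain: Chain, chrom: str, start: int, end: int, direction: str = FORWARD
) -> List[Tuple[int, int]]:
    """Map an interval to the ordered images of its block-covered pieces.

    The total mapped length never exceeds ``end - start``; pieces falling in
    gaps are simply absent from the output.
    """
    _check_direction(direction)
    if start >= end:
        raise ValueError(f"start must be < end, got [{start}, {end})")
    if chrom not in chain.blocks:
        raise KeyError(f"chromosome {chrom!r} not in chain")
    starts, ends, other = chain._index(chrom, direction)
    out: List[Tuple[int, int]] = []
    i = max(0, int(np.searchsorted(starts, start, side="right")) - 1)
    for j in range(i, len(starts)):
        if starts[j] >= end:
            break
        lo = max(start, int(starts[j]))
        hi = min(end, int(ends[j]))
        if lo < hi:
            off = int(other[j]) - int(starts[j])
            out.append((lo + off, hi + off))
    return out


class LiftStatus(Enum):
    LIFTED = "LIFTED"
    UNMAPPED = "UNMAPPED"
    REF_CHANGED = "REF_CHANGED"


@dataclass
class LiftResult:
    status: LiftStatus
    variant: Optional[object] = None  # io_formats.VariantRecord when lifted
    reason: str = ""


def lift_variant(
    chain: Chain,
    target_sequences,
    variant,
    direction: str = FORWARD,
    source_sequences=None,
) -> LiftResult:
    """Lift a VCF-style variant through the chain and re-read its alleles.

    The whole reference span of the variant must fall inside a single chain
    block; variants partially overlapping a block edge are UNMAPPED rather
    than truncated (truncation would silently change alleles).  When the
    target carries a different base at the lifted site (the consensus
    absorbed an allele) the record is re-expressed against the new reference
    allele and flagged REF_CHANGED — a formerly hom-ALT genotype then becomes
    hom-REF and the variant effectively vanishes.
    """
    _check_direction(direction)
    chrom, pos, ref = variant.chrom, variant.pos, variant.ref
    if source_sequences is not None:
        src = source_sequences[chrom]
        if src[pos : pos + len(ref)] != ref:
            raise ValueError(
                f"allele mismatch at {chrom}:{pos}: variant ref {ref!r} vs sequence "
                f"{src[pos:pos + len(ref)]!r}"
            )
    if chrom not in chain.blocks:
        return LiftResult(LiftStatus.UNMAPPED, reason=f"chromosome {chrom!r} not in chain")
    starts, ends, other = chain._index(chrom, direction)
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i < 0 or pos >= ends[i]:
        return LiftResult(LiftStatus.UNMAPPED, reason="position in unalignable gap")
    if pos + len(ref) > ends[i]:
        return LiftResult(LiftStatus.UNMAPPED, reason="span crosses a block edge")
    new_pos = int(other[i] + (pos - starts[i]))
    tseq = target_sequences[chrom]
    new_ref = tseq[new_pos : new_pos + len(ref)]
    if new_ref == ref:
        lifted = replace(variant, pos=new_pos)
        return LiftResult(LiftStatus.LIFTED, variant=lifted)
    # Re-express every allele against the changed reference base(s).
    old_alleles = [ref, *variant.alts]
    new_alts = [a for a in old_alleles if a != new_ref]
    index_of = {a: k + 1 for k, a in enumerate(new_alts)}
    index_of[new_ref] = 0
    new_gts = {}
    for sample, gt in variant.genotypes.items():
        new_gts[sample] = tuple(
            None if a is None else index_of[old_alleles[a]] for a in gt
        )
    lifted = replace(
        variant, pos=new_pos, ref=new_ref, alts=tuple(new_alts), genotypes=new_gts
    )
    return LiftResult(LiftStatus.REF_CHANGED, variant=lifted)


def lift_records(
    chain: Chain,
    target_sequences,
    records: Sequence,
    direction: str = FORWARD,
) -> Tuple[List, List[Tuple[object, str]]]:
    """Lift many records; return (lifted records, rejects with reasons)."""
    lifted: List = []
    rejects: List[Tuple[object, str]] = []
    for rec in records:
        res = lift_variant(chain, target_sequences, rec, direction=direction)
        if res.status is LiftStatus.UNMAPPED:
            rejects.append((rec, res.reason))
        else:
            lifted.append(res.variant)
    return lifted, rejects
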