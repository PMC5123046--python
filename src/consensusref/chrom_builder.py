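"""Rule-based chromosome construction from scaffolds and alignment anchors.

Scaffolds are assigned to chromosomes in three passes mirroring the
anchor-count thresholds of the source procedure: a primary pass admits
scaffolds (>= 10 kb) with at least 7 anchors on one chromosome, a rescue
pass re-admits leftovers at a threshold of 4 (optionally from a re-aligned
anchor set), and small scaffolds (< 10 kb) are placed only on
maximum-quality (254) alignments.  Gaps between ordered scaffolds are
estimated from the reference coordinates; overlapping or abutting
placements receive a fixed 10 kb gap, 10 kb N pads are added at both
chromosome ends as telomeric stand-ins, and unassigned scaffolds are
concatenated into an artificial chrUn with fixed spacers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .io_formats import AGPRow, Anchor, SequenceSet, revcomp

logger = logging.getLogger(__name__)

PRIMARY = "primary"
RESCUE = "rescue"
SMALL = "small"

DEFAULT_OVERLAP_GAP = 10_000
DEFAULT_PAD = 10_000
DEFAULT_SPACER = 10_000


@dataclass(frozen=True)
class Placement:
    """An oriented scaffold-on-chromosome assignment summarised from anchors."""

    scaffold: str
    chrom: str
    start: int
    end: int
    orientation: str  # '+' | '-'
    anchor_count: int
    placement_pass: str  # primary | rescue | small

    def __post_init__(self) -> None:
        if self.anchor_count < 1:
            raise ValueError("placements require at least one anchor")
        if self.start >= self.end:
            raise ValueError("placement interval must be non-empty")


def _pick_chrom(anchors: Sequence[Anchor]) -> Optional[Tuple[str, List[Anchor]]]:
    """Best chromosome by anchor count; a tie is an unresolved conflict."""
    by_chrom: Dict[str, List[Anchor]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    if not by_chrom:
        return None
    best = max(len(v) for v in by_chrom.values())
    winners = [c for c, v in by_chrom.items() if len(v) == best]
    if len(winners) > 1:
        logger.warning(
            "conflicting placements with equal anchor counts on %s; leaving unplaced",
            winners,
        )
        return None
    chrom = winners[0]
    return chrom, by_chrom[chrom]


def _placement_from(scaffold: str, chrom: str, anchors: Sequence[Anchor],
                    placement_pass: str) -> Placement:
    plus = sum(1 for a in anchors if a.strand == "+")
    minus = len(anchors) - plus
    if plus == minus:
        logger.warning("orientation tie for %s on %s; defaulting to '+'", scaffold, chrom)
    orientation = "+" if plus >= minus else "-"
    return Placement(
        scaffold=scaffold,
        chrom=chrom,
        start=min(a.t_start for a in anchors),
        end=max(a.t_end for a in anchors),
        orientation=orientation,
        anchor_count=len(anchors),
        placement_pass=placement_pass,
    )


def place_scaffolds(
    anchors: Sequence[Anchor],
    scaffold_lengths: Mapping[str, int],
    rescue_anchors: Optional[Sequence[Anchor]] = None,
    primary_min_anchors: int = 7,
    rescue_min_anchors: int = 4,
    small_max_len: int = 10_000,
    small_quality: int = 254,
) -> Tuple[List[Placement], List[str]]:
    """Assign scaffolds to chromosomes; returns (placements, unplaced names).

    ``rescue_anchors`` defaults to the primary anchor set; supplying a
    separate set models a re-alignment of the scaffolds that failed the
    primary threshold.
    """
    by_scaf: Dict[str, List[Anchor]] = {}
    for a in anchors:
        if a.scaffold not in scaffold_lengths:
            raise KeyError(f"anchor references unknown scaffold {a.scaffold!r}")
        by_scaf.setdefault(a.scaffold, []).append(a)
    rescue_by_scaf: Dict[str, List[Anchor]] = {}
    for a in (rescue_anchors if rescue_anchors is not None else anchors):
        rescue_by_scaf.setdefault(a.scaffold, []).append(a)

    placements: List[Placement] = []
    unplaced: List[str] = []
    for scaffold, length in scaffold_lengths.items():
        if length >= small_max_len:
            choice = _pick_chrom(by_scaf.get(scaffold, []))
            if choice is not None and len(choice[1]) >= primary_min_anchors:
                placements.append(_placement_from(scaffold, *choice, PRIMARY))
                continue
            choice = _pick_chrom(rescue_by_scaf.get(scaffold, []))
            if choice is not None and len(choice[1]) >= rescue_min_anchors:
                placements.append(_placement_from(scaffold, *choice, RESCUE))
                continue
            unplaced.append(scaffold)
        else:
            hq = [a for a in by_scaf.get(scaffold, []) if a.quality == small_quality]
            choice = _pick_chrom(hq)
            if choice is not None:
                placements.append(_placement_from(scaffold, *choice, SMALL))
            else:
                unplaced.append(scaffold)
    return placements, unplaced


def estimate_gaps(placements: Sequence[Placement],
                  overlap_gap: int = DEFAULT_OVERLAP_GAP) -> List[int]:
    """Inter-scaffold gap sizes for placements ordered along one chromosome.

    The gap is the reference-coordinate distance between consecutive
    placements when positive; overlapping *or abutting* placements receive
    the fixed fallback (AGP gap rows must have positive length, so
    zero-distance abutment is folded into the overlap rule).
    """
    chroms = {p.chrom for p in placements}
    if len(chroms) > 1:
        raise ValueError(f"placements span multiple chromosomes: {sorted(chroms)}")
    gaps = []
    for prev, nxt in zip(placements, placements[1:]):
        if nxt.start < prev.start:
            raise ValueError("placements must be sorted by target start")
        distance = nxt.start - prev.end
        gaps.append(distance if distance > 0 else overlap_gap)
    return gaps


def build_chromosomes(
    placements: Sequence[Placement],
    scaffold_sequences: SequenceSet,
    unplaced: Sequence[str] = (),
    pad: int = DEFAULT_PAD,
    spacer: int = DEFAULT_SPACER,
    overlap_gap: int = DEFAULT_OVERLAP_GAP,
    chrun_name: str = "chrUn",
) -> Tuple[SequenceSet, List[AGPRow]]:
    """Assemble chromosome sequences and the AGP that reproduces them.

    Each chromosome is ``N*pad + scaffolds joined by estimated N gaps +
    N*pad`` with minus-orientation scaffolds reverse-complemented; unplaced
    scaffolds are concatenated into ``chrun_name`` with fixed N spacers.
    The emitted AGP rows rebuild the sequences byte-for-byte.
    """
    for p in placements:
        if p.scaffold not in scaffold_sequences:
            raise KeyError(f"missing sequence for placed scaffold {p.scaffold!r}")
    for name in unplaced:
        if name not in scaffold_sequences:
            raise KeyError(f"missing sequence for unplaced scaffold {name!r}")

    by_chrom: Dict[str, List[Placement]] = {}
    for p in placements:
        by_chrom.setdefault(p.chrom, []).append(p)

    out = SequenceSet()
    agp: List[AGPRow] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end, p.scaffold))
        gaps = estimate_gaps(ordered, overlap_gap=overlap_gap)
        parts: List[str] = []
        rows: List[AGPRow] = []
        cursor = 0
        part_no = 1

        def _gap(length: int, gap_type: str) -> None:
            nonlocal cursor, part_no
            parts.append("N" * length)
            rows.append(AGPRow(chrom, cursor, cursor + length, part_no, "N",
                               gap_length=length, gap_type=gap_type,
                               linkage="no" if gap_type == "telomere" else "yes"))
            cursor += length
            part_no += 1

        _gap(pad, "telomere")
        for i, p in enumerate(ordered):
            seq = scaffold_sequences[p.scaffold]
            oriented = seq if p.orientation == "+" else revcomp(seq)
            parts.append(oriented)
            rows.append(AGPRow(chrom, cursor, cursor + len(seq), part_no, "W",
                               comp_id=p.scaffold, comp_beg=0, comp_end=len(seq),
                               orientation=p.orientation))
            cursor += len(seq)
            part_no += 1
            if i < len(gaps):
                _gap(gaps[i], "scaffold")
        _gap(pad, "telomere")
        out.add(chrom, "".join(parts))
        agp.extend(rows)

    if unplaced:
        parts = []
        rows = []
        cursor = 0
        part_no = 1
        for i, name in enumerate(unplaced):
            seq = scaffold_sequences[name]
            parts.append(seq)
            rows.append(AGPRow(chrun_name, cursor, cursor + len(seq), part_no, "W",
                               comp_id=name, comp_beg=0, comp_end=len(seq),
                               orientation="+"))
            cursor += len(seq)
            part_no += 1
            if i + 1 < len(unplaced):
                parts.append("N" * spacer)
                rows.append(AGPRow(chrun_name, cursor, cursor + spacer, part_no, "N",
                                   gap_length=spacer, gap_type="contig", linkage="no"))
                cursor += spacer
                part_no += 1
        out.add(chrun_name, "".join(parts))
        agp.extend(rows)
    return out, agp


def reconstruct_from_agp(
    rows: Sequence[AGPRow],
    scaffold_sequences: SequenceSet,
) -> SequenceSet:
    """Rebuild object sequences from AGP rows (the round-trip oracle)."""
    objects: Dict[str, List[Tuple[int, str]]] = {}
    for r in rows:
        if r.comp_type == "W":
            seq = scaffold_sequences[r.comp_id][r.comp_beg:r.comp_end]
            if r.orientation == "-":
                seq = revcomp(seq)
        else:
            seq = "N" * r.gap_length
        if len(seq) != r.end - r.beg:
            raise ValueError(
                f"AGP row {r.obj}:{r.beg}-{r.end} length disagrees with component"
            )
        objects.setdefault(r.obj, []).append((r.beg, seq))
    out = SequenceSet()
    for obj, pieces in objects.items():
        pieces.sort()
        cursor = 0
        chunks = []
        for beg, seq in pieces:
            if beg != cursor:
                raise ValueError(f"AGP rows for {obj!r} are not contiguous at {beg}")
            chunks.append(seq)
            cursor = beg + len(seq)
        out.add(obj, "".join(chunks))
    return out
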