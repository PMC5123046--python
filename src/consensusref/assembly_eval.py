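"""Assembly statistics: Nxx/Lxx, gap fraction, recovery rate, novel regions.

Nxx is the largest fragment length L such that fragments of length >= L sum
to at least xx% of the included assembly length; Lxx is the number of such
fragments.  The denominator is by default the total length of fragments
passing the inclusion cutoff (the ">= 200 bp" table convention); gap
percentages support either the assembly total or a supplied expected genome
size, since published tables mix both conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import SequenceSet, _open_text

DEFAULT_XS = (50, 60, 70, 80, 90)


def nxx_lxx(
    lengths: Iterable[int],
    x: float,
    min_len: int = 200,
) -> Tuple[int, int]:
    """Return (Nxx length, Lxx count) for fragments passing ``min_len``.

    The denominator is the summed length of included fragments.
    """
    if not 0 < x < 100:
        raise ValueError(f"x must be in (0, 100), got {x}")
    incl = sorted((int(v) for v in lengths if v >= min_len), reverse=True)
    if not incl:
        raise ValueError(f"no fragments of length >= {min_len}")
    if incl[-1] <= 0:
        raise ValueError("fragment lengths must be positive")
    total = sum(incl)
    cum = 0
    for length in incl:
        cum += length
        if 100 * cum >= x * total:
            lxx = sum(1 for v in incl if v >= length)
            return length, lxx
    raise AssertionError("unreachable: cumulative sum covers the total")


@dataclass
class AssemblyStats:
    """Nxx/Lxx table plus totals and gap fraction for one assembly."""

    nxx: Dict[int, int]
    lxx: Dict[int, int]
    longest: int
    n_fragments: int
    total_length: int          # included fragments only
    total_ge_10kb: int
    gap_percent: float
    min_len: int = 200

    def __post_init__(self) -> None:
        xs = sorted(self.nxx)
        for lo, hi in zip(xs, xs[1:]):
            assert self.nxx[hi] <= self.nxx[lo] and self.lxx[hi] >= self.lxx[lo]


def assembly_stats(
    sequences: SequenceSet,
    xs: Sequence[int] = DEFAULT_XS,
    min_len: int = 200,
) -> AssemblyStats:
    lengths = [len(s) for s in sequences.sequences.values()]
    incl = [v for v in lengths if v >= min_len]
    if not incl:
        raise ValueError(f"no fragments of length >= {min_len}")
    nxx, lxx = {}, {}
    for x in xs:
        nxx[x], lxx[x] = nxx_lxx(incl, x, min_len=min_len)
    return AssemblyStats(
        nxx=nxx,
        lxx=lxx,
        longest=max(incl),
        n_fragments=len(incl),
        total_length=sum(incl),
        total_ge_10kb=sum(v for v in incl if v >= 10_000),
        gap_percent=gap_fraction(sequences),
        min_len=min_len,
    )


def gap_fraction(
    sequences: SequenceSet,
    denominator_mode: str = "assembly",
    expected_size: Optional[float] = None,
) -> float:
    """Percentage of N bases, against assembly total or expected genome size."""
    n_bases = sum(s.count("N") for s in sequences.sequences.values())
    if denominator_mode == "assembly":
        denom = sum(len(s) for s in sequences.sequences.values())
    elif denominator_mode == "genome":
        if expected_size is None:
            raise ValueError("expected_size is required in 'genome' mode")
        denom = expected_size
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    return 100.0 * n_bases / denom


def _merge(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s >= e:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _intersect(
    a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def nongap_intervals(sequences: SequenceSet) -> Dict[str, List[Tuple[int, int]]]:
    """Maximal non-N runs of each sequence."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    for name, seq in sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8) != ord("N")
        out[name] = _runs(arr)
    return out


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open intervals."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(map(int, starts), map(int, ends)))


def recovery_rate(
    alignment_intervals: Mapping[str, Sequence[Tuple[int, int]]],
    reference: SequenceSet,
) -> float:
    """Percentage of the reference's non-gap bases covered by the alignments.

    Intervals may overlap or be split arbitrarily; the union is intersected
    with the non-gap mask and divided by the non-gap length.  Never exceeds
    100%.
    """
    mask = nongap_intervals(reference)
    mask_len = sum(e - s for ivs in mask.values() for s, e in ivs)
    if mask_len == 0:
        raise ValueError("reference has no non-gap bases")
    covered = 0
    for chrom, ivs in alignment_intervals.items():
        if chrom not in reference:
            raise KeyError(f"unknown reference sequence {chrom!r}")
        limit = len(reference[chrom])
        for s, e in ivs:
            if e > limit or s < 0:
                raise ValueError(f"interval [{s},{e}) beyond end of {chrom!r} ({limit})")
        merged = _merge(ivs)
        covered += sum(e - s for s, e in _intersect(merged, mask.get(chrom, [])))
    return 100.0 * covered / mask_len


# ---------------------------------------------------------------------------
# Coverage and novel regions
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-base integer depth per chromosome."""

    depths: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.depths.items():
            arr = np.asarray(arr, dtype=np.int64)
            if (arr < 0).any():
                raise ValueError(f"negative depth on {chrom!r}")
            self.depths[chrom] = arr

    @classmethod
    def from_intervals(
        cls,
        intervals: Mapping[str, Sequence[Tuple[int, int]]],
        lengths: Mapping[str, int],
    ) -> "CoverageTrack":
        """Depth from stacked read intervals (BED-like, 0-based half-open)."""
        depths = {}
        for chrom, length in lengths.items():
            diff = np.zeros(length + 1, dtype=np.int64)
            for s, e in intervals.get(chrom, ()):
                if not 0 <= s <= e <= length:
                    raise ValueError(f"interval [{s},{e}) outside {chrom!r}")
                diff[s] += 1
                diff[e] -= 1
            depths[chrom] = np.cumsum(diff[:-1])
        return cls(depths)

    @classmethod
    def from_bedgraph(cls, path, lengths: Mapping[str, int]) -> "CoverageTrack":
        depths = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
        with _open_text(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split()[:4]
                if chrom not in depths:
                    raise KeyError(f"unknown chromosome {chrom!r} in bedgraph")
                depths[chrom][int(s):int(e)] = int(v)
        return cls(depths)


def novel_regions(
    coverage: CoverageTrack,
    min_depth: int = 3,
    min_len: int = 100,
) -> Dict[str, List[Tuple[int, int]]]:
    """Maximal runs with depth >= ``min_depth`` and length >= ``min_len``.

    Both thresholds are inclusive: a 100 bp run at depth exactly 3
    qualifies under the defaults.  Runs separated by even a single
    below-threshold base are not merged.
    """
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, depth in coverage.depths.items():
        runs = _runs(depth >= min_depth)
        out[chrom] = [(s, e) for s, e in runs if e - s >= min_len]
    return out
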