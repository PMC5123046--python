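"""Structural-variant concordance, filtering and enrichment.

Two SVs are "the same" when they have the same type and are reciprocally
50% covered (each record's span covered to at least half of its own length
by the intersection; boundary equality counts).  Insertions have no
reference extent, so their identity uses breakpoint proximity within a
window plus a reciprocal length ratio of at least 0.5 — a documented
interpretation of the reciprocal rule for zero-span records.

Spurious, misassembly-derived SVs are filtered by comparing the ratio of
single-end-mapped to properly-paired reads (S/P ratio) over the SV region
against the genome-wide ratio with Fisher's exact test: an SV is discarded
only when the test is significant (default P < 0.001) *and* the region's
S/P ratio is inflated — authentic SVs are covered by properly paired reads,
spurious ones by wrongly mapped single-end reads.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .io_formats import SVRecord

#: Relative tolerance when comparing point probabilities against the
#: observed table's probability in the two-sided test.
_REL_TOL = 1e-7

#: Above this grand total the exact integer path switches to log-space pmf.
_EXACT_N_MAX = 2000


@dataclass(frozen=True)
class SPCounts:
    """Single-end and properly-paired read counts over a region."""

    single: int
    paired: int

    def __post_init__(self) -> None:
        if self.single < 0 or self.paired < 0:
            raise ValueError("read counts must be non-negative")


def fisher_exact(table: Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Fisher's exact test for a 2x2 table.

    The two-sided p-value sums the probabilities of all tables with the
    observed margins whose point probability does not exceed the observed
    one (with a small relative tolerance on the comparison).  Small tables
    use exact integer arithmetic; large ones a hypergeometric pmf sum.
    An all-zero table returns 1.0 with a warning.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError(f"table cells must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        warnings.warn("all-zero contingency table; p-value defined as 1", stacklevel=2)
        return 1.0
    r1, r2, c1 = a + b, c + d, a + c
    k_min, k_max = max(0, c1 - r2), min(c1, r1)

    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    if n <= _EXACT_N_MAX:
        weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k)
                   for k in range(k_min, k_max + 1)}
        total = sum(weights.values())
        if alternative == "greater":
            num = sum(w for k, w in weights.items() if k >= a)
        elif alternative == "less":
            num = sum(w for k, w in weights.items() if k <= a)
        else:
            w_obs = weights[a]
            # integer-exact version of w <= w_obs * (1 + 1e-7)
            scale = 10 ** 7
            num = sum(w for w in weights.values() if w * scale <= w_obs * (scale + 1))
        return num / total

    # large margins: hypergeometric pmf over the support in log space
    ks = np.arange(k_min, k_max + 1)

    def logcomb(m, j):
        return gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)

    logpmf = logcomb(r1, ks) + logcomb(r2, c1 - ks) - logcomb(n, c1)
    if alternative == "greater":
        return float(min(1.0, np.exp(logpmf[ks >= a]).sum()))
    if alternative == "less":
        return float(min(1.0, np.exp(logpmf[ks <= a]).sum()))
    log_obs = float(logpmf[a - k_min])
    keep = logpmf <= log_obs + np.log1p(_REL_TOL)
    return float(min(1.0, np.exp(logpmf[keep]).sum()))


def sp_filter(
    sv_counts: SPCounts,
    genome_counts: SPCounts,
    alpha: float = 0.001,
) -> bool:
    """Return True (keep) unless the region's S/P ratio is significantly inflated.

    Discards only in the inflated direction: a significantly *deflated*
    single-end fraction never discards.  A region with zero paired reads is
    maximal inflation and is discarded whenever the test is significant.
    """
    p = fisher_exact(
        [[sv_counts.single, sv_counts.paired],
         [genome_counts.single, genome_counts.paired]]
    )
    inflated = (
        sv_counts.single * genome_counts.paired
        > genome_counts.single * sv_counts.paired
    )
    return not (p < alpha and inflated)


def sv_same(a: SVRecord, b: SVRecord, ins_window: int = 1000) -> bool:
    """Reciprocal-50% identity: same type and each span at least half covered.

    All comparisons are exact integer arithmetic, so the 50% boundary counts
    as covered.  Insertions match on breakpoint distance (within
    ``ins_window``) and reciprocal length ratio >= 0.5.
    """
    if a.sv_type != b.sv_type or a.chrom != b.chrom:
        return False
    if a.sv_type == "INS":
        if abs(a.start - b.start) > ins_window:
            return False
        lo, hi = sorted((a.sv_length, b.sv_length))
        return 2 * lo >= hi
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return False
    return 2 * overlap >= a.sv_length and 2 * overlap >= b.sv_length


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass
class SharingDecomposition:
    """Exclusive sharing groups: each SV cluster belongs to exactly one subset."""

    group_counts: Dict[FrozenSet[str], int]
    clusters: List[List[Tuple[str, SVRecord]]]


def cluster_shared(
    sv_sets: Mapping[str, Sequence[SVRecord]],
    ins_window: int = 1000,
) -> SharingDecomposition:
    """Decompose labelled SV sets into exclusive sharing groups.

    Single-linkage connected components over :func:`sv_same`; each cluster
    is assigned to the (maximal) set of labels that contributed a record, so
    group counts over all label subsets sum to the number of distinct SV
    clusters.  The result is invariant to the input order of sets and
    records, since connected components are order-free.
    """
    if len(sv_sets) < 2:
        raise ValueError("need at least two labelled SV sets")
    items: List[Tuple[str, SVRecord]] = [
        (label, sv) for label in sv_sets for sv in sv_sets[label]
    ]
    order = sorted(range(len(items)),
                   key=lambda i: (items[i][1].chrom, items[i][1].sv_type,
                                  items[i][1].start, items[i][1].end))
    uf = _UnionFind(len(items))
    # sweep within (chrom, type) buckets sorted by start
    for bi in range(len(order)):
        i = order[bi]
        _, a = items[i]
        max_reach = a.end if a.sv_type != "INS" else a.start + ins_window + 1
        for bj in range(bi + 1, len(order)):
            j = order[bj]
            _, b = items[j]
            if (b.chrom, b.sv_type) != (a.chrom, a.sv_type) or b.start >= max_reach:
                break
            if sv_same(a, b, ins_window=ins_window):
                uf.union(i, j)
    clusters: Dict[int, List[Tuple[str, SVRecord]]] = {}
    for i, item in enumerate(items):
        clusters.setdefault(uf.find(i), []).append(item)
    counts: Counter = Counter()
    cluster_list = []
    for members in clusters.values():
        labels = frozenset(label for label, _ in members)
        counts[labels] += 1
        cluster_list.append(members)
    return SharingDecomposition(dict(counts), cluster_list)


def annotate_novel(
    svs: Sequence[SVRecord],
    known_sets: Mapping[str, Sequence[SVRecord]],
    ins_window: int = 1000,
) -> List[bool]:
    """Flag each SV as novel iff it matches no record in any known database.

    Matching uses the same reciprocal-50% identity as everywhere else, so an
    SV sitting exactly at the 50% boundary against a database record counts
    as known.
    """
    buckets: Dict[Tuple[str, str], List[SVRecord]] = {}
    for records in known_sets.values():
        for sv in records:
            buckets.setdefault((sv.chrom, sv.sv_type), []).append(sv)
    for key in buckets:
        buckets[key].sort(key=lambda s: s.start)
    reach: Dict[Tuple[str, str], int] = {
        key: max((s.end - s.start for s in records), default=0)
        for key, records in buckets.items()
    }
    flags = []
    for sv in svs:
        key = (sv.chrom, sv.sv_type)
        candidates = buckets.get(key, [])
        window = max(reach.get(key, 0), ins_window)
        novel = True
        for known in candidates:
            if known.start > sv.end + window:
                break
            if known.end + window < sv.start:
                continue
            if sv_same(sv, known, ins_window=ins_window):
                novel = False
                break
        flags.append(novel)
    return flags


@dataclass(frozen=True)
class EnrichmentResult:
    p_value: float
    enriched: bool


def group_enrichment(
    presence: Sequence[Tuple[int, int, int, int]],
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Per-SV two-group frequency enrichment via Fisher's exact test.

    ``presence`` holds ``(k_in, n_in, k_out, n_out)`` carrier counts for
    each SV.  An SV is enriched when the two-sided p-value is below
    ``alpha`` *and* the in-group carrier frequency is the higher one.
    """
    out = []
    for k_in, n_in, k_out, n_out in presence:
        if n_in <= 0 or n_out <= 0:
            raise ValueError("both groups must be non-empty")
        if not (0 <= k_in <= n_in and 0 <= k_out <= n_out):
            raise ValueError(f"carrier counts outside group sizes: {(k_in, n_in, k_out, n_out)}")
        p = fisher_exact([[k_in, n_in - k_in], [k_out, n_out - k_out]])
        enriched = p < alpha and k_in * n_out > k_out * n_in
        out.append(EnrichmentResult(p, enriched))
    return out
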