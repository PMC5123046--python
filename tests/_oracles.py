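"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: edits are applied by
naive right-to-left string splicing, position maps by base-by-base replay,
Fisher p-values by exact fixed-margin enumeration with rational arithmetic,
and Nxx by a direct cumulative scan.
"""

from __future__ import annotations

from math import comb
from typing import List, Optional, Sequence, Tuple

import numpy as np

from consensusref.consensus import Edit


def splice_oracle(seq: str, edits: Sequence[Edit]) -> str:
    """Apply edits by naive string splicing, rightmost first."""
    out = seq
    for e in sorted(edits, key=lambda e: (e.pos, e.pos + len(e.ref)), reverse=True):
        assert out[e.pos : e.pos + len(e.ref)] == e.ref
        out = out[: e.pos] + e.alt + out[e.pos + len(e.ref) :]
    return out


def replay_positions(seq_len: int, edits: Sequence[Edit]) -> np.ndarray:
    """Per-base source->target map by direct replay (-1 for deleted bases)."""
    out = np.full(seq_len, -1, dtype=np.int64)
    ordered = sorted(edits, key=lambda e: (e.pos, e.pos + len(e.ref)))
    t = 0
    pos = 0
    ei = 0
    while pos < seq_len:
        if ei < len(ordered) and ordered[ei].pos == pos:
            e = ordered[ei]
            ei += 1
            if len(e.ref) == len(e.alt):  # substitution: bases stay aligned
                for k in range(len(e.ref)):
                    out[pos + k] = t + k
                pos += len(e.ref)
                t += len(e.alt)
            else:  # deleted span unmapped; inserted run consumes target only
                pos += len(e.ref)
                t += len(e.alt)
        else:
            out[pos] = t
            pos += 1
            t += 1
    return out


def random_edit_script(
    rng: np.random.Generator, seq: str, n_edits: int = 40, max_indel: int = 8
) -> List[Edit]:
    """A random valid edit script: spaced SNVs, deletions and insertions."""
    edits: List[Edit] = []
    if len(seq) < 40:
        return edits
    spacing = max_indel + 2
    candidates = np.arange(1, len(seq) - max_indel - 1, spacing)
    n = min(n_edits, candidates.size)
    positions = np.sort(rng.choice(candidates, size=n, replace=False))
    for pos in map(int, positions):
        kind = rng.integers(0, 3)
        if kind == 0:  # SNV
            ref = seq[pos]
            alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
            edits.append(Edit(pos, ref, alt, "SNV"))
        elif kind == 1:  # deletion
            k = int(rng.integers(1, max_indel + 1))
            edits.append(Edit(pos, seq[pos : pos + k], "", "INDEL"))
        else:  # insertion
            k = int(rng.integers(1, max_indel + 1))
            ins = "".join(rng.choice(list("ACGT"), size=k))
            edits.append(Edit(pos, "", ins, "INDEL"))
    return edits


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive fixed-margin enumeration (exact ints)."""
    r1, r2, c1 = a + b, c + d, a + c
    ks = range(max(0, c1 - r2), min(c1, r1) + 1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in ks}
    total = sum(weights.values())
    if total == 0:
        return 1.0
    w_obs = weights[a]
    scale = 10 ** 7
    num = sum(w for w in weights.values() if w * scale <= w_obs * (scale + 1))
    return num / total


def nxx_oracle(lengths: Sequence[int], x: float) -> Tuple[int, int]:
    """Largest L with sum(fragments >= L) >= x% of total, by direct scan."""
    values = sorted(set(lengths), reverse=True)
    total = sum(lengths)
    best = None
    for L in values:
        covered = sum(v for v in lengths if v >= L)
        if 100 * covered >= x * total:
            best = L
            break
    assert best is not None
    return best, sum(1 for v in lengths if v >= best)


def depth_runs_oracle(depth: np.ndarray, min_depth: int, min_len: int):
    """Thresholded-depth regions by a per-base boolean scan."""
    regions = []
    start: Optional[int] = None
    for i, v in enumerate(depth):
        if v >= min_depth and start is None:
            start = i
        elif v < min_depth and start is not None:
            if i - start >= min_len:
                regions.append((start, i))
            start = None
    if start is not None and len(depth) - start >= min_len:
        regions.append((start, len(depth)))
    return regions
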