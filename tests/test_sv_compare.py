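"""SV identity, sharing decomposition, S/P filtering and enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

import consensusref as cr
from consensusref.io_formats import SVRecord
from consensusref.sv_compare import (
    SPCounts,
    annotate_novel,
    cluster_shared,
    fisher_exact,
    group_enrichment,
    sp_filter,
    sv_same,
)

from _oracles import fisher_two_sided_oracle


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_balanced_table_is_one():
    assert fisher_exact([[5, 5], [5, 5]]) == 1.0


def test_fisher_extreme_table_matches_enumeration():
    a = fisher_exact([[0, 10], [10, 0]])
    assert a == pytest.approx(fisher_two_sided_oracle(0, 10, 10, 0), abs=1e-12)


def test_fisher_directional_example():
    assert fisher_exact([[9, 2], [1, 9]]) < 0.05


def test_fisher_all_zero_table_warns_and_returns_one():
    with pytest.warns(UserWarning):
        assert fisher_exact([[0, 0], [0, 0]]) == 1.0


def test_fisher_rejects_negative_cells():
    with pytest.raises(ValueError):
        fisher_exact([[1, -1], [2, 3]])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 30)] * 4))
def test_fisher_matches_enumeration_oracle(cells):
    a, b, c, d = cells
    if a + b + c + d == 0:
        return
    assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
        fisher_two_sided_oracle(a, b, c, d), abs=1e-10)


def test_fisher_large_margin_path_matches_scipy():
    for table in ([[50, 50], [1000, 99000]], [[3, 197], [1000, 99000]],
                  [[0, 150], [1000, 99000]]):
        assert fisher_exact(table) == pytest.approx(
            scipy_fisher(table).pvalue, rel=1e-9, abs=1e-300)


def test_fisher_one_sided_matches_scipy(rng):
    for _ in range(50):
        t = rng.integers(0, 25, size=4)
        if t.sum() == 0:
            continue
        table = [[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]]
        for alt in ("greater", "less"):
            assert fisher_exact(table, alternative=alt) == pytest.approx(
                scipy_fisher(table, alternative=alt).pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# S/P filter
# ---------------------------------------------------------------------------

GENOME = SPCounts(1000, 99000)


@pytest.mark.parametrize(
    "sv, keep",
    [
        (SPCounts(50, 50), False),  # strongly single-end inflated: discard
        (SPCounts(1, 99), True),    # at the genome-wide ratio: keep
        (SPCounts(0, 80), True),    # deflated direction never discards
    ],
)
def test_sp_filter_examples(sv, keep):
    assert sp_filter(sv, GENOME) is keep


def test_sp_filter_zero_paired_is_maximal_inflation():
    assert sp_filter(SPCounts(40, 0), GENOME) is False
    assert sp_filter(SPCounts(0, 0), GENOME) is True  # empty region: keep


def test_sp_filter_operating_characteristics():
    """Authentic regions at the genome ratio are retained, 10x-inflated
    spurious regions discarded, both at >=95% (seeded)."""
    df, genome = cr.simulate_sp_counts(n_authentic=200, n_spurious=200, seed=7)
    keep = np.array([sp_filter(SPCounts(int(r.single), int(r.paired)), genome)
                     for r in df.itertuples(index=False)])
    auth = df.authentic.to_numpy()
    assert keep[auth].mean() >= 0.95
    assert (~keep[~auth]).mean() >= 0.95


# ---------------------------------------------------------------------------
# SV identity
# ---------------------------------------------------------------------------

def test_sv_same_reciprocal_boundary():
    a = SVRecord("c", 100, 200, "DEL", 100)
    assert sv_same(a, SVRecord("c", 150, 250, "DEL", 100))       # exactly 50%
    assert not sv_same(a, SVRecord("c", 151, 250, "DEL", 99))    # 49%
    assert not sv_same(a, SVRecord("c", 100, 200, "INV", 100))   # type mismatch


def test_sv_same_requires_reciprocity():
    small = SVRecord("c", 100, 200, "DEL", 100)
    big = SVRecord("c", 0, 1000, "DEL", 1000)
    assert not sv_same(small, big)  # 100% of small but 10% of big


def test_sv_same_insertions_window_and_length_ratio():
    a = SVRecord("c", 500, 500, "INS", 300)
    assert sv_same(a, SVRecord("c", 1500, 1500, "INS", 300))        # window edge
    assert not sv_same(a, SVRecord("c", 1501, 1501, "INS", 300))
    assert sv_same(a, SVRecord("c", 600, 600, "INS", 150))          # ratio 0.5
    assert not sv_same(a, SVRecord("c", 600, 600, "INS", 149))


def test_sv_same_symmetric_and_reflexive(rng):
    types = ["DEL", "INV", "INS"]
    records = []
    for _ in range(60):
        t = types[int(rng.integers(3))]
        s = int(rng.integers(0, 5000))
        ln = int(rng.integers(50, 800))
        records.append(SVRecord("c", s, s if t == "INS" else s + ln, t, ln))
    for a in records:
        assert sv_same(a, a)
    for a in records[:30]:
        for b in records[30:]:
            assert sv_same(a, b) == sv_same(b, a)


# ---------------------------------------------------------------------------
# sharing decomposition
# ---------------------------------------------------------------------------

def test_cluster_pair_is_counted_once():
    sets = {
        "1": [SVRecord("c", 100, 300, "DEL", 200, "1")],
        "2": [SVRecord("c", 120, 320, "DEL", 200, "2")],
        "3": [SVRecord("c", 9000, 9200, "DEL", 200, "3")],
    }
    dec = cluster_shared(sets)
    assert dec.group_counts == {frozenset({"1", "2"}): 1, frozenset({"3"}): 1}


def test_cluster_recovers_planted_design():
    sets, truth = cr.simulate_sv_universe(seed=3)
    dec = cluster_shared(sets)
    assert dec.group_counts == truth
    assert sum(dec.group_counts.values()) == len(dec.clusters)


def test_cluster_matches_allpairs_oracle_and_order_invariance(rng):
    sets, _ = cr.simulate_sv_universe(seed=5)
    dec = cluster_shared(sets)

    # brute-force single-linkage over all pairs
    items = [(lab, sv) for lab in sets for sv in sets[lab]]
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if sv_same(items[i][1], items[j][1]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    from collections import Counter
    oracle = Counter()
    groups = {}
    for i, (lab, _) in enumerate(items):
        groups.setdefault(find(i), set()).add(lab)
    for labels in groups.values():
        oracle[frozenset(labels)] += 1
    assert dec.group_counts == dict(oracle)

    # shuffling sets and records does not change the decomposition
    shuffled = {}
    for lab in rng.permutation(sorted(sets)):
        records = list(sets[lab])
        rng.shuffle(records)
        shuffled[str(lab)] = records
    assert cluster_shared(shuffled).group_counts == dec.group_counts


def test_singleton_cluster():
    sets = {"1": [SVRecord("c", 100, 300, "DEL", 200, "1")], "2": []}
    dec = cluster_shared(sets)
    assert dec.group_counts == {frozenset({"1"}): 1}


# ---------------------------------------------------------------------------
# novelty
# ---------------------------------------------------------------------------

def test_novel_boundary_and_empty_known():
    sv = SVRecord("c", 100, 200, "DEL", 100)
    known_exact_boundary = SVRecord("c", 150, 250, "DEL", 100)
    assert annotate_novel([sv], {"db": [known_exact_boundary]}) == [False]
    assert annotate_novel([sv], {}) == [True]


def test_novel_flags_match_allpairs_oracle(rng):
    svs, known = [], []
    for _ in range(150):
        s = int(rng.integers(0, 50_000))
        ln = int(rng.integers(60, 500))
        t = ["DEL", "INV", "INS"][int(rng.integers(3))]
        rec = SVRecord("c", s, s if t == "INS" else s + ln, t, ln)
        (svs if rng.random() < 0.5 else known).append(rec)
    flags = annotate_novel(svs, {"db": known})
    oracle = [not any(sv_same(sv, k) for k in known) for sv in svs]
    assert flags == oracle


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_group_enrichment_rules():
    results = group_enrichment([
        (11, 11, 0, 10),   # all Asian carriers, none outside: enriched
        (5, 11, 5, 10),    # similar frequencies: not enriched
        (0, 11, 10, 10),   # significant but wrong direction: not enriched
    ])
    assert [r.enriched for r in results] == [True, False, False]
    assert results[0].p_value < 0.05
    assert results[2].p_value < 0.05  # significant, direction rule rejects


def test_group_enrichment_empty_group_raises():
    with pytest.raises(ValueError):
        group_enrichment([(1, 0, 1, 10)])
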