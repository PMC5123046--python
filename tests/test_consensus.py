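"""Consensus construction: tallies, selection rules, edit application."""

import numpy as np
import pytest

import consensusref as cr
from consensusref.consensus import (
    Edit,
    EditError,
    EditScript,
    PloidyError,
    PloidyScheme,
    SubstitutionPolicy,
    apply_edits,
    build_consensus,
    normalize_variant,
    resolve_conflicts,
    select_indel_substitutions,
    select_snv_substitutions,
    tally_alleles,
)
from consensusref.io_formats import SequenceSet, VariantRecord

from _oracles import random_edit_script, replay_positions, splice_oracle


def _snv_record(genotypes, chrom="chr1", pos=10, ref="A", alt="G"):
    return VariantRecord(chrom, pos, ref, (alt,), genotypes)


def _scheme(n=40, n_male=25):
    sexes = {f"S{i:02d}": ("M" if i < n_male else "F") for i in range(n)}
    return PloidyScheme(sexes)


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------

def test_tally_all_het_cohort():
    """40 diploids all 0/1 give 40 ref + 40 alt haploids over 80 called."""
    scheme = _scheme()
    gts = {s: (0, 1) for s in scheme.samples}
    (t,) = tally_alleles([_snv_record(gts)], scheme)
    assert t.counts == {"A": 40, "G": 40}
    assert (t.called, t.total) == (80, 80)


def test_tally_missing_samples_shrink_called_not_total():
    scheme = _scheme()
    gts = {s: (0, 1) for s in scheme.samples}
    for s in scheme.samples[:2]:
        gts[s] = (None, None)
    (t,) = tally_alleles([_snv_record(gts)], scheme)
    assert (t.called, t.total) == (76, 80)
    assert sum(t.counts.values()) == t.called


def test_tally_y_chromosome_capacity_is_male_haploids():
    """Y sites are tallied over 25 male haploids in the 25M/15F cohort."""
    scheme = _scheme()
    gts = {}
    for s, sex in scheme.sexes.items():
        gts[s] = (1,) if sex == "M" else (None,)
    (t,) = tally_alleles([_snv_record(gts, chrom="chrY")], scheme)
    assert t.total == 25
    assert t.counts["G"] == 25
    # X capacity comes from the 15 females only
    assert scheme.capacity("chrX") == 30


def test_tally_rejects_arity_conflicts():
    scheme = _scheme()
    gts = {s: (0, 1) for s in scheme.samples}
    gts[scheme.samples[0]] = (1,)  # haploid call on an autosome
    with pytest.raises(PloidyError, match="arity"):
        tally_alleles([_snv_record(gts)], scheme)


def test_tally_multiallelic_site_counts_all_bases():
    scheme = PloidyScheme.all_diploid(["a", "b", "c"])
    rec = VariantRecord("chr1", 5, "A", ("G", "T"),
                        {"a": (1, 2), "b": (0, 1), "c": (2, 2)})
    (t,) = tally_alleles([rec], scheme)
    assert t.counts == {"A": 1, "G": 2, "T": 3}
    assert t.called == 6


def test_tally_aggregates_indel_representations():
    """The same deletion in two VCF representations is one tallied event."""
    seq = SequenceSet({"chr1": "ACGTTTTACGT"})
    scheme = PloidyScheme.all_diploid(["a", "b"])
    # both records delete one T from the T-run; both left-align to pos 3
    rec1 = VariantRecord("chr1", 3, "TT", ("T",), {"a": (1, 1), "b": (0, 0)})
    rec2 = VariantRecord("chr1", 5, "TT", ("T",), {"a": (0, 0), "b": (0, 1)})
    tallies = tally_alleles([rec1, rec2], scheme, reference=seq)
    indels = [t for t in tallies if t.kind == "INDEL"]
    assert len(indels) == 1
    assert indels[0].pos == 3 and indels[0].support == 3


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------

def _snv_tally(counts, ref="A", total=80):
    called = sum(counts.values())
    return cr.CohortSiteTally("chr1", 10, ref, "SNV", counts, called, total)


@pytest.mark.parametrize(
    "counts, expect_edit",
    [
        ({"A": 30, "G": 50}, "G"),   # major allele differs -> substitute
        ({"A": 40, "G": 40}, None),  # tie keeps the reference
        ({"A": 50, "G": 30}, None),  # reference already major
        ({"A": 10, "G": 30, "T": 30}, None),  # tied alts: no unique major
    ],
)
def test_snv_selection_rule(counts, expect_edit):
    edits = select_snv_substitutions([_snv_tally(counts)])
    if expect_edit is None:
        assert edits == {}
    else:
        assert edits["chr1"] == [Edit(10, "A", expect_edit, "SNV")]


def test_snv_selection_empty_input():
    assert select_snv_substitutions([]) == {}


def _indel_tally(support, total, called=None, pos=20):
    called = called if called is not None else total
    counts = {"T": support, "TA": called - support}
    return cr.CohortSiteTally("chr1", pos, "TA", "INDEL", counts, called, total,
                              alt="T")


@pytest.mark.parametrize(
    "support, total, substituted",
    [
        (41, 80, True),   # strictly over half of 80 haploids
        (40, 80, False),  # exactly half: not substituted
        (16, 30, True),   # X-chromosome capacity 30 (15 females)
        (15, 30, False),
    ],
)
def test_indel_threshold_is_strict_over_half_capacity(support, total, substituted):
    edits = select_indel_substitutions([_indel_tally(support, total)])
    assert bool(edits) is substituted


def test_indel_threshold_monotonicity():
    """Raising the threshold never increases the number of indel edits."""
    tallies = [_indel_tally(s, 80, pos=20 + 10 * i) for i, s in enumerate(range(30, 60))]
    counts = []
    for fraction in (0.3, 0.4, 0.5, 0.6, 0.7):
        edits = select_indel_substitutions(tallies, SubstitutionPolicy(fraction))
        counts.append(sum(len(v) for v in edits.values()))
    assert counts == sorted(counts, reverse=True)


def test_conflicting_indel_is_dropped_and_logged():
    snv = {"chr1": [Edit(5, "A", "G", "SNV")]}
    indel = {"chr1": [Edit(4, "TAC", "", "INDEL"), Edit(50, "G", "", "INDEL")]}
    script, dropped = resolve_conflicts(snv, indel)
    assert [e.pos for e in script.edits["chr1"]] == [5, 50]
    assert len(dropped) == 1 and dropped[0][1].pos == 4


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pos, ref, alt, expected",
    [
        (2, "AA", "A", (2, "A", "")),     # anchored deletion trims to atomic
        (3, "A", "", (2, "A", "")),       # right-edge deletion left-aligns
        (3, "", "A", (2, "", "A")),       # insertion left-aligns through run
        (3, "GTC", "GGC", (4, "T", "G")), # MNP trims to the changed base
        (5, "C", "G", (5, "C", "G")),     # SNV unchanged
    ],
)
def test_normalize_variant(pos, ref, alt, expected):
    seq = "ACAATAGCGT"
    assert normalize_variant(seq, pos, ref, alt) == expected


# ---------------------------------------------------------------------------
# apply_edits
# ---------------------------------------------------------------------------

def test_apply_no_edits_gives_identity():
    ref = SequenceSet({"c": "ACGTACGT"})
    cons, chain = apply_edits(ref, EditScript({}))
    assert cons == ref
    assert chain.blocks["c"] == [(0, 8, 0, 8)]


def test_apply_edits_mixed_example():
    ref = SequenceSet({"c": "ACGTACGT"})
    script = EditScript({"c": [Edit(2, "G", "T", "SNV"), Edit(4, "AC", "", "INDEL")]})
    cons, chain = apply_edits(ref, script)
    assert cons["c"] == "ACTTGT"
    assert chain.blocks["c"] == [(0, 4, 0, 4), (6, 8, 4, 6)]


def test_apply_edits_insertion_splice():
    ref = SequenceSet({"c": "AAAA"})
    cons, _ = apply_edits(ref, EditScript({"c": [Edit(3, "", "GG", "INDEL")]}))
    assert cons["c"] == "AAAGGA"


def test_apply_edits_ref_mismatch_aborts_with_position():
    ref = SequenceSet({"c": "ACGT"})
    with pytest.raises(EditError, match="c:1"):
        apply_edits(ref, EditScript({"c": [Edit(1, "G", "T", "SNV")]}))


def test_apply_edits_matches_splice_oracle(rng):
    """Random scripts on random references equal naive splicing; the chain
    agrees base-by-base with an edit-replay position oracle."""
    for _ in range(30):
        n = int(rng.integers(100, 5000))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        edits = random_edit_script(rng, seq, n_edits=int(rng.integers(0, 30)))
        ref = SequenceSet({"c": seq})
        cons, chain = apply_edits(ref, EditScript({"c": edits}))
        assert cons["c"] == splice_oracle(seq, edits)
        for s0, s1, t0, t1 in chain.blocks["c"]:
            assert s1 - s0 == t1 - t0
        oracle = replay_positions(n, edits)
        mapped = cr.map_positions(chain, "c", np.arange(n))
        assert np.array_equal(mapped, oracle)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def test_build_consensus_recovers_planted_truth(small_cohort):
    sim = small_cohort
    res = build_consensus(sim.reference, sim.records, sim.scheme)
    truth = sim.truth
    expect = {
        (r.chrom, r.pos, r.ref, r.alt)
        for r in truth[truth.substituted].itertuples(index=False)
    }
    got = {
        (chrom, e.pos, e.ref, e.alt)
        for chrom, edits in res.script.edits.items()
        for e in edits
    }
    assert got == expect
    # report lists haploid support for every applied edit
    applied = res.report[res.report.status == "applied"]
    assert len(applied) == len(expect)
    assert (applied.support > 0).all()


def test_build_consensus_idempotent_on_consensus_cohort(small_cohort):
    """A cohort homozygous for the consensus alleles yields zero edits."""
    sim = small_cohort
    res = build_consensus(sim.reference, sim.records, sim.scheme)
    cohort2 = []
    for rec in sim.records:
        lifted = cr.lift_variant(res.chain, res.consensus, rec)
        if lifted.status is cr.LiftStatus.UNMAPPED:
            continue
        var = lifted.variant
        gts = {s: (0, 0) for s in sim.samples}  # hom for the consensus allele
        cohort2.append(cr.VariantRecord(var.chrom, var.pos, var.ref, var.alts, gts))
    res2 = build_consensus(res.consensus, cohort2, sim.scheme)
    assert res2.script.total_edits() == 0
    assert res2.consensus == res.consensus


def test_build_consensus_identical_cohort_no_edits():
    ref = SequenceSet({"chr1": "ACGTACGTAC"})
    scheme = PloidyScheme.all_diploid(["a", "b"])
    rec = VariantRecord("chr1", 4, "A", ("G",), {"a": (0, 0), "b": (0, 0)})
    res = build_consensus(ref, [rec], scheme)
    assert res.script.total_edits() == 0
    assert res.consensus == ref
    assert res.chain.blocks["chr1"] == [(0, 10, 0, 10)]


def test_build_consensus_indel_boundary_pair():
    """A 41/80 indel is substituted, a 40/80 indel is not."""
    ref = SequenceSet({"chr1": "ACGTACGTACGTACGTACGT"})
    samples = [f"S{i:02d}" for i in range(40)]
    scheme = PloidyScheme.all_diploid(samples)

    def gts(support):
        out = {}
        remaining = support
        for s in samples:
            take = min(2, remaining)
            out[s] = tuple([1] * take + [0] * (2 - take))
            remaining -= take
        return out

    rec41 = VariantRecord("chr1", 4, "AC", ("A",), gts(41))
    rec40 = VariantRecord("chr1", 12, "AC", ("A",), gts(40))
    res = build_consensus(ref, [rec41, rec40], scheme)
    edits = res.script.edits["chr1"]
    assert len(edits) == 1 and edits[0].kind == "INDEL"
    assert edits[0].pos == 5
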