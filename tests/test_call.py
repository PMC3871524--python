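"""Tallying, the mutational-call criteria and co-occurrence reporting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplicall import refdata
from amplicall.align import Observation
from amplicall.call import (
    CallCriteria,
    VariantTally,
    call_variants,
    cooccurrence,
    process_reads,
    tally,
)
from amplicall.demux import ReadBin, design_grid
from amplicall.refdata import VariantKey
from amplicall.simulate import SampleSpec, SimConfig, VariantSpec, simulate_reads

SNV = VariantKey(2361, 2361, "G", "A")
DEL = VariantKey(2236, 2250, "GAATTAAGAGAAGCA", "")


def make_bin(n_reads, sample="A", exon=20):
    return ReadBin(sample, exon, [(f"r{i}", "NNN", "forward") for i in range(n_reads)])


def brute_force_call(t: VariantTally, c: CallCriteria) -> bool:
    """Direct re-evaluation of the four written conditions."""
    n = t.fwd_count + t.rev_count
    cond_reads = n >= c.min_reads
    cond_fraction = round(100.0 * n / t.total_reads,
                          c.fraction_rounding_decimals) >= 100.0 * c.min_fraction
    cond_strands = (not c.require_both_strands) or (t.fwd_count >= 1 and t.rev_count >= 1)
    cond_homopolymer = not (t.homopolymer_flag and t.variant_key.is_indel)
    return cond_reads and cond_fraction and cond_strands and cond_homopolymer


class TestTally:
    def test_strand_split_counts(self):
        bin = make_bin(2359)
        obs = [Observation(f"r{i}", "forward", SNV, False) for i in range(12)]
        obs += [Observation(f"r{i}", "reverse", SNV, False) for i in range(12, 23)]
        t, = tally(bin, obs)
        assert (t.fwd_count, t.rev_count, t.total_reads) == (12, 11, 2359)

    def test_duplicate_observations_count_once(self):
        bin = make_bin(10)
        obs = [Observation("r0", "forward", SNV, False)] * 3
        obs += [Observation("r1", "reverse", SNV, False)]
        t, = tally(bin, obs)
        # brute-force oracle: distinct (read, variant) pairs
        assert t.support == len({(o.read_id, o.variant_key) for o in obs}) == 2

    def test_empty_bin_empty_tallies(self):
        assert tally(make_bin(0), []) == []

    def test_unknown_read_errors(self):
        with pytest.raises(ValueError, match="unknown read"):
            tally(make_bin(2), [Observation("zz", "forward", SNV, False)])

    def test_homopolymer_flag_only_for_indels(self):
        bin = make_bin(100)
        obs = [
            Observation("r0", "forward", SNV, True),
            Observation("r1", "reverse", DEL, True),
        ]
        tallies = {t.variant_key: t for t in tally(bin, obs)}
        assert not tallies[SNV].homopolymer_flag
        assert tallies[DEL].homopolymer_flag


class TestCallCriteria:
    @pytest.mark.parametrize(
        "fwd,rev,total,called,reasons",
        [
            (12, 11, 2359, True, set()),       # 0.975% rounds to 1%
            (4, 3, 750, False, {"below_min_reads"}),
            (30, 0, 1000, False, {"single_strand"}),
            (3, 2, 2000, False, {"below_min_reads", "below_min_fraction"}),
        ],
    )
    def test_call_examples(self, fwd, rev, total, called, reasons):
        t = VariantTally(SNV, fwd, rev, total)
        c, = call_variants([t])
        assert c.called is called
        assert set(c.filter_reasons) == reasons
        assert c.mutated_read_percent == pytest.approx(100.0 * (fwd + rev) / total)

    def test_percent_rounds_to_one(self):
        c, = call_variants([VariantTally(SNV, 12, 11, 2359)])
        assert round(c.mutated_read_percent, 1) == 1.0

    def test_homopolymer_indel_never_called_even_dual_strand(self):
        t = VariantTally(DEL, 40, 40, 400, homopolymer_flag=True)
        c, = call_variants([t])
        assert not c.called
        assert "homopolymer_artifact" in c.filter_reasons

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError):
            call_variants([VariantTally(SNV, 0, 0, 0)])

    def test_called_iff_no_filter_reasons(self):
        for t in [VariantTally(SNV, 12, 11, 2359), VariantTally(SNV, 1, 0, 10)]:
            c, = call_variants([t])
            assert c.called == (not c.filter_reasons)


@st.composite
def tallies(draw):
    depth = draw(st.integers(min_value=1, max_value=50))
    fwd = draw(st.integers(min_value=0, max_value=depth))
    rev = draw(st.integers(min_value=0, max_value=depth - fwd))
    indel = draw(st.booleans())
    hp = draw(st.booleans())
    key = DEL if indel else SNV
    return VariantTally(key, fwd, rev, depth, homopolymer_flag=hp and indel)


@given(t=tallies())
@settings(max_examples=300, deadline=None, derandomize=True)
def test_caller_equals_bruteforce_reevaluation(t):
    criteria = CallCriteria()
    c, = call_variants([t], criteria)
    assert c.called == brute_force_call(t, criteria)


@given(t=tallies(), extra=st.integers(min_value=1, max_value=20))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_monotone_in_support(t, extra):
    """Raising supporting counts at fixed depth never un-calls a variant."""
    criteria = CallCriteria()
    base, = call_variants([t], criteria)
    if base.called:
        boosted = VariantTally(
            t.variant_key,
            min(t.fwd_count + extra, t.total_reads - t.rev_count),
            t.rev_count, t.total_reads, t.homopolymer_flag,
        )
        c, = call_variants([boosted], criteria)
        assert c.called


@given(t=tallies(), extra_depth=st.integers(min_value=1, max_value=500))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_monotone_in_depth(t, extra_depth):
    """Raising depth at fixed counts never turns a negative into a call."""
    criteria = CallCriteria()
    base, = call_variants([t], criteria)
    deeper = VariantTally(t.variant_key, t.fwd_count, t.rev_count,
                          t.total_reads + extra_depth, t.homopolymer_flag)
    deep, = call_variants([deeper], criteria)
    if not base.called:
        assert not deep.called


class TestCooccurrence:
    def _pipeline(self, variants, depth=400, seed=8, amplicons=None):
        exon21 = [a for a in amplicons if a.exon_id == 21]
        grid = design_grid(1, refdata.DEFAULT_MID_INVENTORY, sample_ids=("A",), exons=(21,))
        config = SimConfig(samples=(SampleSpec("A", variants),), depth_per_target=depth,
                           homopolymer_indel_rate=0.0, substitution_error_rate=0.0,
                           seed=seed)
        reads, _ = simulate_reads(config, grid, exon21)
        from amplicall.call import process_bin
        from amplicall.demux import demultiplex

        result = demultiplex(reads, grid, exon21)
        return process_bin(result.bins[("A", 21)], exon21[0])

    def test_same_allele_shares_reads(self, amplicons):
        v1 = VariantSpec(21, "snv", 2573, 2573, "G", 0.4, haplotype=1)
        v2 = VariantSpec(21, "snv", 2533, 2533, "A", 0.4, haplotype=1)
        calls, obs = self._pipeline((v1, v2), amplicons=amplicons)
        row, = cooccurrence(calls, obs)
        assert row.in_haplotype
        assert row.shared_reads == min(c.tally.support for c in calls if c.called)
        assert row.same_clone_compatible

    def test_disjoint_clones_share_nothing(self, amplicons):
        v1 = VariantSpec(21, "snv", 2573, 2573, "G", 0.3)
        v2 = VariantSpec(21, "snv", 2533, 2533, "A", 0.3)
        calls, obs = self._pipeline((v1, v2), amplicons=amplicons)
        row, = cooccurrence(calls, obs)
        assert row.shared_reads == 0
        assert not row.in_haplotype

    def test_equal_fractions_same_clone_compatible(self):
        a = VariantTally(VariantKey(2369, 2369, "C", "T"), 55, 49, 400)
        b = VariantTally(VariantKey(2573, 2573, "T", "G"), 52, 52, 400)
        calls = call_variants([a, b])
        obs = []
        rows = cooccurrence(calls, obs)
        assert rows[0].same_clone_compatible  # 26% vs 26%
        c = VariantTally(VariantKey(2071, 2071, "C", "A"), 5, 5, 400)  # 2.5%
        rows = cooccurrence(call_variants([a, c]), obs)
        assert not rows[0].same_clone_compatible


def test_replicate_runs_agree(amplicons):
    """Two independently simulated replicates of one mutated sample yield the
    same call set with similar mutated-read percentages at depth >= 500."""
    grid = design_grid(1, refdata.DEFAULT_MID_INVENTORY, sample_ids=("A",))
    spec = (VariantSpec(21, "snv", 2573, 2573, "G", 0.2),
            VariantSpec(19, "deletion", 2236, 2250, "", 0.35))
    results = []
    for seed in (101, 202):
        config = SimConfig(samples=(SampleSpec("A", spec),), depth_per_target=600,
                           seed=seed)
        reads, _ = simulate_reads(config, grid, amplicons)
        calls, _ = process_reads(reads, grid, amplicons)
        results.append({
            c.variant_key: c.mutated_read_percent
            for calls_ in calls.values() for c in calls_ if c.called
        })
    first, second = results
    assert set(first) == set(second)
    for key in first:
        assert abs(first[key] - second[key]) < 6.0
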