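"""Read simulator: determinism, fraction recovery, noise models."""

import filecmp

import numpy as np
import pytest

from amplicall import refdata
from amplicall.demux import demultiplex, design_grid
from amplicall.simulate import (
    SampleSpec,
    SimConfig,
    VariantSpec,
    inject_homopolymer_noise,
    purity_to_fraction,
    simulate_reads,
    simulate_run,
    variant_read_counts,
)
from conftest import make_amplicon

L858R = VariantSpec(exon_id=21, kind="snv", cds_start=2573, cds_end=2573,
                    alt="G", allele_fraction=0.3)


@pytest.mark.parametrize(
    "purity,copies,ploidy,expected",
    [(0.40, 1, 2, 0.20), (1.0, 2, 2, 1.0), (0.05, 1, 2, 0.025)],
)
def test_purity_to_fraction(purity, copies, ploidy, expected):
    assert purity_to_fraction(purity, copies, ploidy) == pytest.approx(expected)


def test_purity_to_fraction_rejects_bad_ploidy():
    with pytest.raises(ValueError):
        purity_to_fraction(0.5, 1, 0)


def test_same_seed_gives_byte_identical_output(tmp_path, amplicons, single_sample_grid):
    config = SimConfig(samples=(SampleSpec("A", (L858R,)),), depth_per_target=60, seed=11)
    for sub in ("one", "two"):
        simulate_run(config, single_sample_grid, amplicons, tmp_path / sub)
    assert filecmp.cmp(tmp_path / "one" / "reads.fastq", tmp_path / "two" / "reads.fastq",
                       shallow=False)
    assert filecmp.cmp(tmp_path / "one" / "truth.tsv", tmp_path / "two" / "truth.tsv",
                       shallow=False)


def test_zero_noise_reads_match_reference(amplicons, single_sample_grid):
    config = SimConfig(
        samples=(SampleSpec("A"),), depth_per_target=100,
        homopolymer_indel_rate=0.0, substitution_error_rate=0.0, seed=1,
    )
    reads, truth = simulate_reads(config, single_sample_grid, amplicons)
    assert len(reads) == 100 * len(amplicons)
    assert truth.empty
    result = demultiplex(reads, single_sample_grid, amplicons)
    assert not result.unassigned
    for (sample, exon), bin in result.bins.items():
        ref = next(a.insert for a in amplicons if a.exon_id == exon)
        for _, insert, strand in bin.reads:
            oriented = refdata.revcomp(insert) if strand == "reverse" else insert
            assert oriented == ref


def test_tumor_purity_sets_nominal_fraction(amplicons, single_sample_grid):
    het = VariantSpec(exon_id=21, kind="snv", cds_start=2573, cds_end=2573, alt="G")
    config = SimConfig(samples=(SampleSpec("A", (het,), tumor_purity=0.40),),
                       depth_per_target=10, seed=2)
    _, truth = simulate_reads(config, single_sample_grid, amplicons)
    assert truth["nominal_fraction"].tolist() == [pytest.approx(0.20)]


def test_variant_outside_amplicon_rejected(amplicons, single_sample_grid):
    bad = VariantSpec(exon_id=18, kind="snv", cds_start=2573, cds_end=2573,
                      alt="G", allele_fraction=0.5)
    config = SimConfig(samples=(SampleSpec("A", (bad,)),), depth_per_target=5, seed=0)
    with pytest.raises(ValueError, match="outside"):
        simulate_reads(config, single_sample_grid, amplicons)


class TestHomopolymerNoise:
    def test_rate_zero_is_identity(self, by_exon):
        amp = by_exon[20]
        rng = np.random.default_rng(0)
        assert inject_homopolymer_noise(amp.insert, amp, 0.0, rng) == amp.insert

    def test_no_eligible_run_means_no_edit(self):
        amp = make_amplicon("GATCTGACCGTCTGCCATTCGGCT")  # no run >= 4
        assert amp.insert_homopolymer_runs() == ()
        rng = np.random.default_rng(0)
        assert inject_homopolymer_noise(amp.insert, amp, 0.999, rng) == amp.insert

    def test_rate_one_single_indel_inside_run(self):
        amp = make_amplicon("GATCAAAATCGGCT" + "GATC")  # one AAAA run
        runs = amp.insert_homopolymer_runs()
        assert len(runs) == 1
        (start, end), = runs
        rng = np.random.default_rng(3)
        for _ in range(20):
            noisy = inject_homopolymer_noise(amp.insert, amp, 1.0, rng)
            assert abs(len(noisy) - len(amp.insert)) == 1
            # direct string-diff oracle: outside-run flanks are untouched
            assert noisy[:start] == amp.insert[:start]
            assert noisy[len(noisy) - (len(amp.insert) - end):] == amp.insert[end:]


def test_fraction_recovery_binomial(amplicons):
    rng = np.random.default_rng(7)
    depth, frac, reps = 2000, 0.1, 150
    counts = variant_read_counts(depth, frac, reps, rng)
    se = np.sqrt(frac * (1 - frac) / depth / reps) * depth
    assert abs(counts.mean() - depth * frac) < 4 * se


def test_strand_balance_converges(amplicons, single_sample_grid):
    config = SimConfig(samples=(SampleSpec("A"),), depth_per_target=2000,
                       strand_balance=0.3, seed=9)
    exon21 = [a for a in amplicons if a.exon_id == 21]
    grid = design_grid(1, refdata.DEFAULT_MID_INVENTORY, sample_ids=("A",), exons=(21,))
    reads, _ = simulate_reads(config, grid, exon21)
    result = demultiplex(reads, grid, exon21)
    fwd = sum(1 for _, _, s in result.bins[("A", 21)].reads if s == "forward")
    se = np.sqrt(0.3 * 0.7 / 2000)
    assert abs(fwd / 2000 - 0.3) < 4 * se


def test_haplotype_clones_share_reads(amplicons, single_sample_grid):
    v1 = VariantSpec(exon_id=21, kind="snv", cds_start=2573, cds_end=2573,
                     alt="G", allele_fraction=0.3, haplotype=1)
    v2 = VariantSpec(exon_id=21, kind="snv", cds_start=2533, cds_end=2533,
                     alt="A", allele_fraction=0.3, haplotype=1)
    config = SimConfig(samples=(SampleSpec("A", (v1, v2)),), depth_per_target=50,
                       homopolymer_indel_rate=0.0, substitution_error_rate=0.0, seed=4)
    exon21 = [a for a in amplicons if a.exon_id == 21]
    grid = design_grid(1, refdata.DEFAULT_MID_INVENTORY, sample_ids=("A",), exons=(21,))
    reads, _ = simulate_reads(config, grid, exon21)
    result = demultiplex(reads, grid, exon21)
    amp = exon21[0]
    i1 = amp.ref_index(2573) - amp.insert_offset
    i2 = amp.ref_index(2533) - amp.insert_offset
    for _, insert, strand in result.bins[("A", 21)].reads:
        oriented = refdata.revcomp(insert) if strand == "reverse" else insert
        # both edits ride the same molecules
        assert (oriented[i1] == "G") == (oriented[i2] == "A")
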