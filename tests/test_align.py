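"""Alignment, indel normalization, observation extraction and naming."""

import numpy as np
import pytest

from amplicall import refdata
from amplicall.align import (
    align_read,
    extract_observations,
    name_variant,
    write_sam,
)
from amplicall.refdata import VariantKey, revcomp


def apply_cds_edit(amp, cds_start, cds_end, alt):
    """Apply an edit (inclusive c. range replaced by alt) to the insert."""
    i0 = amp.ref_index(cds_start) - amp.insert_offset
    i1 = amp.ref_index(cds_end) - amp.insert_offset + 1
    return amp.insert[:i0] + alt + amp.insert[i1:]


def observations_for(insert, amp, strand="forward"):
    ar = align_read(insert, amp, strand)
    return extract_observations(ar, amp)


def test_identity_alignment_has_no_edits(by_exon):
    amp = by_exon[20]
    ar = align_read(amp.insert, amp, "forward")
    assert ar.edit_distance == 0
    assert ar.path == (("=", len(amp.insert)),)
    assert observations_for(amp.insert, amp) == []


def test_substitution_at_polymorphism_site(by_exon):
    amp = by_exon[20]
    insert = apply_cds_edit(amp, 2361, 2361, "A")
    obs, = observations_for(insert, amp)
    assert obs.variant_key == VariantKey(2361, 2361, "G", "A")
    assert not obs.in_homopolymer
    cds, protein = name_variant(obs.variant_key, amp)
    assert (cds, protein) == ("c.2361G>A", "Q787Q")


def test_exon19_15bp_deletion_single_left_aligned_run(by_exon):
    amp = by_exon[19]
    insert = apply_cds_edit(amp, 2236, 2250, "")
    ar = align_read(insert, amp, "forward")
    assert sum(1 for op, _ in ar.path if op == "D") == 1
    assert ("D", 15) in ar.path
    obs, = observations_for(insert, amp)
    key = obs.variant_key
    assert (key.cds_start, len(key.ref), key.alt) == (2236, 15, "")
    # brute-force oracle: leftmost equivalent placement of a 15-bp deletion
    ref = amp.insert
    equivalent = [
        p for p in range(len(ref) - 15 + 1)
        if ref[:p] + ref[p + 15:] == insert
    ]
    leftmost_cds = amp.cds_coord(min(equivalent) + amp.insert_offset)
    assert key.cds_start == leftmost_cds
    assert name_variant(key, amp) == ("c.2236_2250del", "del E746-A750")
    assert not obs.in_homopolymer


@pytest.mark.parametrize("length", [1, 2, 3, 5, 6])
def test_deletions_left_aligned_bruteforce(by_exon, length):
    """Every deletion's reported start equals the minimum over all
    alignment-equivalent placements (exhaustive oracle)."""
    amp = by_exon[19]
    ref = amp.insert
    rng = np.random.default_rng(length)
    for start in rng.choice(len(ref) - length - 6, size=12, replace=False):
        start = int(start) + 3
        mutated = ref[:start] + ref[start + length:]
        obs = observations_for(mutated, amp)
        if not obs:  # edit cancelled by sequence context
            continue
        key = obs[0].variant_key
        equivalent = [
            p for p in range(len(ref) - length + 1)
            if ref[:p] + ref[p + length:] == mutated
        ]
        assert amp.ref_index(key.cds_start) - amp.insert_offset == min(equivalent)


def test_delins_merged_into_single_event(by_exon):
    amp = by_exon[19]
    insert = apply_cds_edit(amp, 2239, 2250, "CCT")  # codons 747-750 -> P
    obs, = observations_for(insert, amp)
    cds, protein = name_variant(obs.variant_key, amp)
    assert protein == "del L747-A750 insP"
    assert "delins" in cds


def test_nearby_edits_merge_within_two_bases(by_exon):
    amp = by_exon[20]
    # two substitutions separated by one reference base
    i = amp.ref_index(2314) - amp.insert_offset
    ref = amp.insert
    insert = ref[:i] + "T" + ref[i + 1] + ("A" if ref[i + 2] != "A" else "C") + ref[i + 3:]
    obs = observations_for(insert, amp)
    assert len(obs) == 1
    key = obs[0].variant_key
    assert len(key.ref) == 3 and len(key.alt) == 3


def test_single_base_deletion_in_adenine_run_flagged(by_exon):
    amp = by_exon[19]
    insert = apply_cds_edit(amp, 2199, 2199, "")  # inside the AAAA run
    obs, = observations_for(insert, amp)
    assert obs.variant_key.is_indel
    assert obs.in_homopolymer


def test_frameshift_marked(by_exon):
    amp = by_exon[21]
    insert = apply_cds_edit(amp, 2573, 2574, "")  # 2-bp deletion
    obs, = observations_for(insert, amp)
    _, protein = name_variant(obs.variant_key, amp)
    assert protein.endswith("fs")


def test_strand_symmetry(by_exon):
    """A read and its reverse complement yield identical variant keys."""
    amp = by_exon[21]
    for cds_start, cds_end, alt in [(2573, 2573, "G"), (2533, 2533, "A"),
                                    (2530, 2541, ""), (2560, 2565, "TAG")]:
        insert = apply_cds_edit(amp, cds_start, cds_end, alt)
        fwd = {o.variant_key for o in observations_for(insert, amp, "forward")}
        rev = {o.variant_key for o in observations_for(revcomp(insert), amp, "reverse")}
        assert fwd and fwd == rev


def test_low_identity_read_unalignable(by_exon):
    amp = by_exon[18]
    garbage = "AC" * (len(amp.insert) // 2)
    ar = align_read(garbage, amp, "forward")
    assert ar.unalignable
    assert extract_observations(ar, amp) == []


@pytest.mark.parametrize(
    "cds_start,cds_end,alt,expected",
    [
        (2573, 2573, "G", "L858R"),
        (2236, 2250, "", "del E746-A750"),
        (2233, 2250, "", "del K745-A750"),
        (2239, 2256, "", "del L747-S752"),
        (2239, 2250, "CCT", "del L747-A750 insP"),
        (2369, 2369, "T", "T790M"),
    ],
)
def test_variant_naming_convention(amplicons, cds_start, cds_end, alt, expected):
    amp = refdata.amplicon_for_cds(amplicons, cds_start)
    insert = apply_cds_edit(amp, cds_start, cds_end, alt)
    obs = observations_for(insert, amp)
    names = {name_variant(o.variant_key, amp)[1] for o in obs}
    assert expected in names


def test_sam_output_parses(tmp_path, by_exon):
    import pysam

    amp = by_exon[21]
    insert = apply_cds_edit(amp, 2573, 2573, "G")
    aligned = [
        ("S1", align_read(amp.insert, amp, "forward", "r1")),
        ("S1", align_read(insert, amp, "forward", "r2")),
        ("S1", align_read(revcomp(insert), amp, "reverse", "r3")),
    ]
    path = tmp_path / "out.sam"
    write_sam(path, [amp], aligned)
    with pysam.AlignmentFile(str(path)) as sam:
        records = list(sam)
    assert [r.query_name for r in records] == ["r1", "r2", "r3"]
    assert records[0].cigarstring == f"{len(amp.insert)}="
    assert records[2].is_reverse
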