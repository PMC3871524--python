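"""Strand-split variant tallying and the mutational-call criteria.

A nucleotide variation is called a mutation only when it is supported by at
least ``min_reads`` reads (default 10) *and* by at least ``min_fraction``
of the target's total reads (default 1%, compared after rounding the
percentage to ``fraction_rounding_decimals`` decimals), is observed on both
DNA strands, and -- for insertions/deletions -- does not touch a reference
homopolymer run of length >= 4 (pyrosequencing length artifacts).  Every
failing condition is recorded as a filter reason.

The percentage comparison defaults to integer-percent precision: the
10-read requirement is the binding criterion at ordinary depths (a 0.975%
observation among 2,359 reads counts as 1% and is called; 7 reads among
750 fail only the 10-read rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import align as align_mod
from . import refdata
from .demux import DemuxResult, ReadBin, demultiplex
from .refdata import AmpliconDef, MutationCatalogEntry, VariantKey

__all__ = [
    "CallCriteria",
    "VariantTally",
    "VariantCall",
    "CooccurrenceRow",
    "tally",
    "call_variants",
    "cooccurrence",
    "process_bin",
    "process_reads",
    "write_vcf",
    "write_calls_tsv",
    "FILTER_REASONS",
]

FILTER_REASONS = (
    "below_min_reads",
    "below_min_fraction",
    "single_strand",
    "homopolymer_artifact",
)


@dataclass(frozen=True)
class CallCriteria:
    """Thresholds defining a positive mutational call."""

    min_reads: int = 10
    min_fraction: float = 0.01
    require_both_strands: bool = True
    homopolymer_min_run: int = 4
    fraction_rounding_decimals: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.homopolymer_min_run < 1:
            raise ValueError("homopolymer_min_run must be >= 1")


@dataclass(frozen=True)
class VariantTally:
    variant_key: VariantKey
    fwd_count: int
    rev_count: int
    total_reads: int
    homopolymer_flag: bool = False

    def __post_init__(self) -> None:
        if min(self.fwd_count, self.rev_count, self.total_reads) < 0:
            raise ValueError("counts must be non-negative")
        if self.fwd_count + self.rev_count > self.total_reads:
            raise ValueError("supporting reads exceed total reads")

    @property
    def support(self) -> int:
        return self.fwd_count + self.rev_count


@dataclass(frozen=True)
class VariantCall:
    tally: VariantTally
    called: bool
    mutated_read_percent: float
    filter_reasons: frozenset
    cds_change: str = ""
    protein_change: str = ""
    annotation: MutationCatalogEntry | None = None

    @property
    def variant_key(self) -> VariantKey:
        return self.tally.variant_key


def tally(bin: ReadBin, observations: Sequence[align_mod.Observation]
          ) -> list[VariantTally]:
    """Aggregate per-read observations into strand-split per-variant tallies.

    One read contributes at most once per variant; the homopolymer flag is
    set for indels with any homopolymer-touching support.
    """
    known = {rid for rid, _, _ in bin.reads}
    seen: set[tuple[str, VariantKey]] = set()
    counts: dict[VariantKey, list] = {}
    for obs in observations:
        if obs.read_id not in known:
            raise ValueError(f"observation references unknown read {obs.read_id!r}")
        dedupe = (obs.read_id, obs.variant_key)
        if dedupe in seen:
            continue
        seen.add(dedupe)
        entry = counts.setdefault(obs.variant_key, [0, 0, False])
        if obs.strand == "forward":
            entry[0] += 1
        else:
            entry[1] += 1
        if obs.in_homopolymer:
            entry[2] = True
    out = []
    for key in sorted(counts):
        fwd, rev, touch = counts[key]
        out.append(
            VariantTally(
                variant_key=key,
                fwd_count=fwd,
                rev_count=rev,
                total_reads=bin.total_reads,
                homopolymer_flag=bool(touch and key.is_indel),
            )
        )
    return out


def call_variants(
    tallies: Iterable[VariantTally],
    criteria: CallCriteria = CallCriteria(),
    amplicon: AmpliconDef | None = None,
    catalog: Sequence[MutationCatalogEntry] | None = None,
) -> list[VariantCall]:
    """Apply the mutational-call criteria to each tally.

    When ``amplicon`` is given, calls are annotated with c./protein names
    and the catalog's TKI-role prediction.
    """
    out = []
    for t in tallies:
        if t.total_reads <= 0:
            raise ValueError("total_reads must be > 0 to call variants")
        reasons = set()
        percent = 100.0 * t.support / t.total_reads
        if t.support < criteria.min_reads:
            reasons.add("below_min_reads")
        if round(percent, criteria.fraction_rounding_decimals) < 100.0 * criteria.min_fraction:
            reasons.add("below_min_fraction")
        if criteria.require_both_strands and (t.fwd_count == 0 or t.rev_count == 0):
            reasons.add("single_strand")
        if t.homopolymer_flag and t.variant_key.is_indel:
            reasons.add("homopolymer_artifact")
        cds = protein = ""
        annotation = None
        if amplicon is not None:
            cds, protein = align_mod.name_variant(t.variant_key, amplicon)
            annotation = refdata.annotate(protein, amplicon.exon_id, catalog)
        out.append(
            VariantCall(
                tally=t,
                called=not reasons,
                mutated_read_percent=percent,
                filter_reasons=frozenset(reasons),
                cds_change=cds,
                protein_change=protein,
                annotation=annotation,
            )
        )
    return out


@dataclass(frozen=True)
class CooccurrenceRow:
    key_a: VariantKey
    key_b: VariantKey
    shared_reads: int
    in_haplotype: bool
    same_clone_compatible: bool
    delta_percent: float


def cooccurrence(
    calls: Sequence[VariantCall],
    observations: Sequence[align_mod.Observation],
    tolerance_percent: float = 2.0,
) -> list[CooccurrenceRow]:
    """Pairwise haplotype report for called variants on one target.

    ``shared_reads`` counts reads supporting both variants (non-zero shared
    support marks the pair as observed in haplotype); two variants whose
    mutated-read percentages agree within ``tolerance_percent`` points are
    flagged compatible with a single neoplastic clone (the default 2-point
    tolerance mirrors the assay's observed run-to-run variation).
    """
    called = [c for c in calls if c.called]
    support: dict[VariantKey, set] = {c.variant_key: set() for c in called}
    for obs in observations:
        if obs.variant_key in support:
            support[obs.variant_key].add(obs.read_id)
    rows = []
    for i in range(len(called)):
        for j in range(i + 1, len(called)):
            a, b = called[i], called[j]
            shared = len(support[a.variant_key] & support[b.variant_key])
            delta = abs(a.mutated_read_percent - b.mutated_read_percent)
            rows.append(
                CooccurrenceRow(
                    key_a=a.variant_key,
                    key_b=b.variant_key,
                    shared_reads=shared,
                    in_haplotype=shared > 0,
                    same_clone_compatible=delta <= tolerance_percent,
                    delta_percent=delta,
                )
            )
    return rows


# --------------------------------------------------------------------------
# pipeline glue

def process_bin(
    bin: ReadBin,
    amplicon: AmpliconDef,
    criteria: CallCriteria = CallCriteria(),
    catalog: Sequence[MutationCatalogEntry] | None = None,
    identity_floor: float = align_mod.DEFAULT_IDENTITY_FLOOR,
) -> tuple[list[VariantCall], list[align_mod.Observation]]:
    """Align one bin's reads, tally and call."""
    observations: list[align_mod.Observation] = []
    for rid, insert, strand in bin.reads:
        if not insert:
            continue
        ar = align_mod.align_read(insert, amplicon, strand, read_id=rid,
                                  identity_floor=identity_floor)
        observations.extend(align_mod.extract_observations(ar, amplicon))
    if bin.total_reads == 0:
        return [], observations
    tallies = tally(bin, observations)
    calls = call_variants(tallies, criteria, amplicon=amplicon, catalog=catalog)
    return calls, observations


def process_reads(
    reads,
    grid,
    amplicons: Sequence[AmpliconDef],
    criteria: CallCriteria = CallCriteria(),
    catalog: Sequence[MutationCatalogEntry] | None = None,
) -> tuple[dict, DemuxResult]:
    """Demultiplex -> align -> tally -> call for a whole run.

    Returns ``(calls_by_target, demux_result)`` with ``calls_by_target``
    mapping ``(sample_id, exon_id)`` to the bin's list of VariantCall.
    """
    by_exon = {a.exon_id: a for a in amplicons}
    result = demultiplex(reads, grid, amplicons)
    calls_by_target = {}
    for (sample, exon), bin in result.bins.items():
        if bin.total_reads == 0:
            calls_by_target[(sample, exon)] = []
            continue
        calls, _ = process_bin(bin, by_exon[exon], criteria, catalog)
        calls_by_target[(sample, exon)] = calls
    return calls_by_target, result


# --------------------------------------------------------------------------
# output

def _vcf_record_coords(key: VariantKey, amplicon: AmpliconDef) -> tuple[int, str, str]:
    """1-based POS, REF, ALT with indel anchoring."""
    seq = amplicon.reference_seq
    i = amplicon.ref_index(key.cds_start)
    if key.ref and key.alt and len(key.ref) == len(key.alt):
        return i + 1, key.ref, key.alt
    if key.ref == "":  # insertion after i
        return i + 1, seq[i], seq[i] + key.alt
    anchor = seq[i - 1]
    return i, anchor + key.ref, anchor + key.alt


def write_vcf(
    path: str | Path,
    calls_by_target: dict,
    amplicons: Sequence[AmpliconDef],
    criteria: CallCriteria = CallCriteria(),
) -> None:
    """Emit calls (including filtered tallies) as VCF 4.2.

    INFO carries DP (bin depth), SAF/SAR (strand-split support), VAF and
    the HP homopolymer flag; FILTER carries the failing call criteria.
    """
    import pysam

    by_exon = {a.exon_id: a for a in amplicons}
    order = sorted(by_exon)
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line('##source=amplicall')
    for e in order:
        header.add_line(
            f'##contig=<ID=EGFR_ex{e}_amplicon,length={len(by_exon[e].reference_seq)}>'
        )
    header.add_line(f'##FILTER=<ID=below_min_reads,Description="Fewer than {criteria.min_reads} supporting reads">')
    header.add_line(f'##FILTER=<ID=below_min_fraction,Description="Below {100 * criteria.min_fraction:g}% of total reads">')
    header.add_line('##FILTER=<ID=single_strand,Description="Support on one strand only">')
    header.add_line(f'##FILTER=<ID=homopolymer_artifact,Description="Indel touching reference homopolymer run >= {criteria.homopolymer_min_run}">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total reads on target">')
    header.add_line('##INFO=<ID=SAF,Number=1,Type=Integer,Description="Supporting reads, forward strand">')
    header.add_line('##INFO=<ID=SAR,Number=1,Type=Integer,Description="Supporting reads, reverse strand">')
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Supporting-read fraction">')
    header.add_line('##INFO=<ID=HP,Number=0,Type=Flag,Description="Touches homopolymer run">')
    header.add_line('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">')
    header.add_line('##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein-level change">')
    with pysam.VariantFile(str(path), "w", header=header) as out:
        records = []
        for (sample, exon), calls in sorted(calls_by_target.items()):
            amp = by_exon[exon]
            for c in calls:
                pos, ref, alt = _vcf_record_coords(c.variant_key, amp)
                records.append((order.index(exon), pos, sample, c, ref, alt))
        records.sort(key=lambda r: (r[0], r[1], r[2]))
        for contig_idx, pos, sample, c, ref, alt in records:
            rec = out.new_record(
                contig=f"EGFR_ex{order[contig_idx]}_amplicon",
                start=pos - 1,
                alleles=(ref, alt),
            )
            rec.info["DP"] = c.tally.total_reads
            rec.info["SAF"] = c.tally.fwd_count
            rec.info["SAR"] = c.tally.rev_count
            rec.info["VAF"] = c.tally.support / c.tally.total_reads
            if c.tally.homopolymer_flag:
                rec.info["HP"] = True
            rec.info["SAMPLE"] = sample
            if c.protein_change:
                rec.info["PCHANGE"] = c.protein_change.replace(" ", "_")
            if c.called:
                rec.filter.add("PASS")
            else:
                for reason in sorted(c.filter_reasons):
                    rec.filter.add(reason)
            out.write(rec)


def write_calls_tsv(path: str | Path, calls_by_target: dict) -> None:
    """Flat per-call table: sample, exon, c./protein change, % mutated
    reads, strand-split support and the TKI-role prediction."""
    with Path(path).open("w") as fh:
        fh.write(
            "sample\texon\tcds_change\tprotein_change\tmutated_read_percent\t"
            "fwd\trev\tdepth\tcalled\tfilters\ttki_prediction\n"
        )
        for (sample, exon), calls in sorted(calls_by_target.items()):
            for c in calls:
                role = c.annotation.tki_role.value if c.annotation else ""
                filters = ";".join(sorted(c.filter_reasons)) or "PASS"
                fh.write(
                    f"{sample}\t{exon}\t{c.cds_change}\t{c.protein_change}\t"
                    f"{c.mutated_read_percent:.2f}\t{c.tally.fwd_count}\t"
                    f"{c.tally.rev_count}\t{c.tally.total_reads}\t"
                    f"{str(c.called).lower()}\t{filters}\t{role}\n"
                )
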