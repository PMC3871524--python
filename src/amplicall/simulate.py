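"""Synthetic MID-tagged amplicon read generation.

Emulates a dual-barcode amplicon deep-sequencing run: every sample x exon
target receives a fixed number of full-length reads (the assay design aims
at ~700 reads per target), each read carrying its forward/reverse MID pair,
a short junction spacer, the PCR primers and the amplicon insert.  Variants
are spiked at nominal allele fractions (dilution series or tumor-purity
mixing); sequencing noise comprises pyrosequencing-style homopolymer
insertions/deletions (restricted to reference homopolymer runs of length
>= 4) and uniform base substitutions.

The generator is fully deterministic given a seed: identical configurations
produce byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import refdata
from .refdata import AmpliconDef, VariantKey, revcomp

__all__ = [
    "VariantSpec",
    "SampleSpec",
    "SimConfig",
    "purity_to_fraction",
    "inject_homopolymer_noise",
    "simulate_reads",
    "simulate_run",
    "variant_read_counts",
    "DEFAULT_SPACER",
]

#: 4-nt junction between the MID tag and the PCR primer (stands in for the
#: platform junction + universal tail, which are configurable, not modelled
#: base-by-base).
DEFAULT_SPACER = "TCAG"

#: qualities are emitted as a constant high value; the call criteria are
#: count-based and never consult base qualities.
_QUAL_CHAR = "I"


def purity_to_fraction(purity: float, copies_mutated: int = 1, ploidy: int = 2) -> float:
    """Expected mutated-allele fraction for a tumor-cell proportion.

    A specimen with 40% neoplastic cells carrying a heterozygous mutation at
    a dysomic locus yields 20% mutated alleles.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if not 0 <= copies_mutated <= ploidy:
        raise ValueError("copies_mutated must be between 0 and ploidy")
    return purity * copies_mutated / ploidy


@dataclass(frozen=True)
class VariantSpec:
    """A variant to spike into simulated reads.

    ``cds_start``/``cds_end`` are inclusive c. coordinates (for an SNV both
    equal the substituted position).  ``alt`` is the replacement sequence
    (empty for a pure deletion).  ``allele_fraction`` may be omitted when
    the sample's ``tumor_purity`` is set, in which case the heterozygous
    dysomic fraction (purity / 2) is used.  Variants sharing a ``haplotype``
    label are placed on the same simulated molecules (one clone).
    """

    exon_id: int
    kind: str  # {"snv", "deletion", "delins"}
    cds_start: int
    cds_end: int
    alt: str = ""
    allele_fraction: float | None = None
    haplotype: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("snv", "deletion", "delins"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.allele_fraction is not None and not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must be in [0, 1]")
        if self.kind == "snv" and (self.cds_start != self.cds_end or len(self.alt) != 1):
            raise ValueError("snv must substitute exactly one base")
        if self.kind == "deletion":
            if self.alt:
                raise ValueError("deletion must have empty alt")
            if self.cds_end < self.cds_start:
                raise ValueError("deletion length must be > 0")

    def raw_key(self, amplicon: AmpliconDef) -> VariantKey:
        ref = amplicon.cds_slice(self.cds_start, self.cds_end)
        return VariantKey(self.cds_start, self.cds_end, ref, self.alt)

    def key(self, amplicon: AmpliconDef) -> VariantKey:
        """Normalized (left-aligned, parsimony-reduced) variant key."""
        return refdata.normalize_variant(amplicon, self.raw_key(amplicon))


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    variants: tuple[VariantSpec, ...] = ()
    tumor_purity: float | None = None


@dataclass(frozen=True)
class SimConfig:
    """Run configuration for the read simulator."""

    samples: tuple[SampleSpec, ...]
    depth_per_target: int = 700
    strand_balance: float = 0.5
    homopolymer_indel_rate: float = 5e-3
    substitution_error_rate: float = 5e-4
    seed: int = 0
    spacer: str = DEFAULT_SPACER

    def __post_init__(self) -> None:
        if self.depth_per_target < 1:
            raise ValueError("depth_per_target must be >= 1")
        if not 0.0 < self.strand_balance < 1.0:
            raise ValueError("strand_balance must be in (0, 1)")
        for rate in (self.homopolymer_indel_rate, self.substitution_error_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("error rates must be in [0, 1)")


def effective_fraction(sample: SampleSpec, variant: VariantSpec) -> float:
    if variant.allele_fraction is not None:
        return variant.allele_fraction
    if sample.tumor_purity is None:
        raise ValueError(
            f"variant in sample {sample.sample_id} has no allele_fraction and no tumor_purity"
        )
    return purity_to_fraction(sample.tumor_purity)


# --------------------------------------------------------------------------
# noise

def _inject_runs(seq: str, runs: Sequence[tuple[int, int]], rate: float,
                 rng: np.random.Generator) -> str:
    if rate <= 0.0 or not runs:
        return seq
    edits: list[tuple[int, str]] = []  # (position, op) op in {"+X", "-"}
    for start, end in runs:
        if rng.random() < rate:
            pos = int(rng.integers(start, end))
            if rng.random() < 0.5:
                edits.append((pos, "+" + seq[start]))
            else:
                edits.append((pos, "-"))
    for pos, op in sorted(edits, reverse=True):
        if op == "-":
            seq = seq[:pos] + seq[pos + 1:]
        else:
            seq = seq[:pos] + op[1] + seq[pos:]
    return seq


def inject_homopolymer_noise(read: str, reference: AmpliconDef, rate: float,
                             rng: np.random.Generator) -> str:
    """Insert or delete one base inside reference homopolymer runs >= 4.

    ``read`` is an insert-coordinate copy of the reference insert; each
    eligible run is hit independently with probability ``rate`` (rate 1
    hits every run).  Bases outside such runs are never edited.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    return _inject_runs(read, reference.insert_homopolymer_runs(), rate, rng)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _inject_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for pos in sorted(int(p) for p in positions):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


# --------------------------------------------------------------------------
# clone assignment

def _clone_groups(sample: SampleSpec, amplicon: AmpliconDef
                  ) -> tuple[list[tuple[VariantSpec, ...]], list[float]]:
    """Group this amplicon's variants into clones and return per-clone
    allele fractions.  Variants sharing a haplotype label form one clone and
    must share one fraction; fractions of distinct clones must sum to <= 1.
    """
    variants = [v for v in sample.variants if v.exon_id == amplicon.exon_id]
    groups: dict[object, list[VariantSpec]] = {}
    for i, v in enumerate(variants):
        keyed = ("hap", v.haplotype) if v.haplotype is not None else ("solo", i)
        groups.setdefault(keyed, []).append(v)
    out_groups, fractions = [], []
    for members in groups.values():
        fracs = {effective_fraction(sample, v) for v in members}
        if len(fracs) > 1:
            raise ValueError("variants on one haplotype must share an allele fraction")
        out_groups.append(tuple(members))
        fractions.append(fracs.pop())
    if sum(fractions) > 1.0 + 1e-9:
        raise ValueError("clone allele fractions sum to more than 1")
    return out_groups, fractions


def assign_clones(rng: np.random.Generator, depth: int,
                  fractions: Sequence[float]) -> np.ndarray:
    """Assign each of ``depth`` reads to a clone (-1 = wild type).

    Clone k receives a read with probability ``fractions[k]``; this is the
    per-read sampling model behind every spiked variant, so the supporting
    read count of a clone is Binomial(depth, fraction).
    """
    draws = rng.random(depth)
    out = np.full(depth, -1, dtype=np.int64)
    lo = 0.0
    for k, f in enumerate(fractions):
        out[(draws >= lo) & (draws < lo + f)] = k
        lo += f
    return out


def variant_read_counts(depth: int, allele_fraction: float, replicates: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Variant-supporting read counts over replicate simulated targets.

    Runs the simulator's per-read clone assignment (``assign_clones``) once
    per replicate and counts the reads carrying the variant.
    """
    counts = np.empty(replicates, dtype=np.int64)
    for i in range(replicates):
        counts[i] = int((assign_clones(rng, depth, [allele_fraction]) == 0).sum())
    return counts


# --------------------------------------------------------------------------
# read generation

def _apply_variants(insert: str, amplicon: AmpliconDef,
                    variants: Sequence[VariantSpec]) -> str:
    """Apply variants (cds coordinates) to the reference insert."""
    edits = []
    for v in variants:
        i0 = amplicon.ref_index(v.cds_start) - amplicon.insert_offset
        i1 = amplicon.ref_index(v.cds_end) - amplicon.insert_offset + 1
        if i0 < 0 or i1 > len(insert):
            raise ValueError(
                f"variant c.{v.cds_start}_{v.cds_end} lies outside the exon "
                f"{amplicon.exon_id} amplicon insert"
            )
        edits.append((i0, i1, v.alt))
    edits.sort(reverse=True)
    for (i0, i1, alt), nxt in zip(edits, edits[1:] + [(-1, -1, "")]):
        if nxt[1] > i0:
            raise ValueError("overlapping variants on one haplotype")
    for i0, i1, alt in edits:
        insert = insert[:i0] + alt + insert[i1:]
    return insert


def simulate_reads(config: SimConfig, grid, amplicons: Sequence[AmpliconDef]
                   ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate reads in memory.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` and ``truth`` is the per-variant truth table
    (sample, exon, cds_change, protein_change, nominal_fraction).

    ``grid`` is a :class:`amplicall.demux.GridScheme`; every sample x exon
    pair must carry a MID pair.
    """
    rng = np.random.default_rng(config.seed)
    spacer = config.spacer
    spacer_rc = revcomp(spacer)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for sample in config.samples:
        for amplicon in amplicons:
            pair = grid.pair_for(amplicon.exon_id, sample.sample_id)
            groups, fractions = _clone_groups(sample, amplicon)
            templates = [
                _apply_variants(amplicon.insert, amplicon, members)
                for members in groups
            ]
            template_runs = [
                refdata.homopolymer_runs(t) for t in templates
            ]
            ref_insert = amplicon.insert
            ref_runs = amplicon.insert_homopolymer_runs()
            for members, frac in zip(groups, fractions):
                for v in members:
                    key = v.key(amplicon)
                    protein, _ = refdata.protein_change_for(amplicon, key)
                    truth_rows.append(
                        dict(
                            sample=sample.sample_id,
                            exon=amplicon.exon_id,
                            cds_change=refdata.cds_change_string(key),
                            protein_change=protein,
                            nominal_fraction=frac,
                            cds_start=key.cds_start,
                            cds_end=key.cds_end,
                            ref=key.ref,
                            alt=key.alt,
                        )
                    )
            clone = assign_clones(rng, config.depth_per_target, fractions)
            forward = rng.random(config.depth_per_target) < config.strand_balance
            left = pair.forward_mid + spacer + amplicon.forward_primer
            right = revcomp(amplicon.reverse_primer) + spacer_rc + revcomp(pair.reverse_mid)
            for i in range(config.depth_per_target):
                k = int(clone[i])
                if k < 0:
                    insert, runs = ref_insert, ref_runs
                else:
                    insert, runs = templates[k], template_runs[k]
                insert = _inject_runs(insert, runs, config.homopolymer_indel_rate, rng)
                insert = _inject_substitutions(insert, config.substitution_error_rate, rng)
                molecule = left + insert + right
                strand = "f" if forward[i] else "r"
                if not forward[i]:
                    molecule = revcomp(molecule)
                rid = f"{sample.sample_id}:ex{amplicon.exon_id}:{i:05d}:{strand}"
                reads.append((rid, molecule))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample", "exon", "cds_change", "protein_change", "nominal_fraction",
            "cds_start", "cds_end", "ref", "alt",
        ],
    )
    return reads, truth


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = (
        SeqRecord(
            Seq(seq), id=rid, description="",
            letter_annotations={"phred_quality": [40] * len(seq)},
        )
        for rid, seq in reads
    )
    seqio_write(records, str(path), "fastq")


def simulate_run(config: SimConfig, grid, amplicons: Sequence[AmpliconDef],
                 out_dir: str | Path) -> tuple[Path, Path]:
    """Simulate a run and write ``reads.fastq`` + ``truth.tsv``.

    Returns the two paths.  Identical configurations (including the seed)
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads, truth = simulate_reads(config, grid, amplicons)
    fastq = out_dir / "reads.fastq"
    write_fastq(reads, fastq)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return fastq, truth_path
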