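"""Read-to-amplicon alignment and per-read variant observation extraction.

Each binned read insert is aligned globally to its amplicon's insert under
fixed affine scores (match +1, mismatch -2, gap open -4, gap extend -1).
Indels are then normalized deterministically: adjacent edits within 2 bp
merge into a single deletion-insertion event, pure indels are shifted to
their leftmost alignment-equivalent placement, and every edit touching a
reference homopolymer run of length >= 4 is flagged (those flags later
drive the pyrosequencing-artifact exclusion for indel calls).

Alignment results are cached per distinct insert sequence; amplicon reads
at depth are dominated by a handful of distinct sequences, so the cache
makes whole-run alignment cheap.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align

from . import refdata
from .refdata import AmpliconDef, VariantKey, revcomp

__all__ = [
    "AlignedRead",
    "Observation",
    "ALIGN_SCORES",
    "DEFAULT_IDENTITY_FLOOR",
    "align_read",
    "extract_observations",
    "name_variant",
    "write_sam",
]

#: fixed alignment scores: (match, mismatch, gap open, gap extend)
ALIGN_SCORES = (1, -2, -4, -1)

#: reads whose alignment identity falls below this are excluded from tallies
DEFAULT_IDENTITY_FLOOR = 0.70

#: adjacent edits separated by at most this many reference bases merge into
#: one deletion-insertion event
MERGE_WINDOW = 2

HOMOPOLYMER_MIN_RUN = 4


@dataclass(frozen=True)
class Observation:
    """One normalized variant seen on one read."""

    read_id: str
    strand: str
    variant_key: VariantKey
    in_homopolymer: bool


@dataclass(frozen=True)
class AlignedRead:
    """Alignment of one read insert against its amplicon insert.

    ``path`` is a run-length encoded alignment path over ops '=' (match),
    'X' (mismatch), 'I' (insertion to the reference) and 'D' (deletion from
    the reference).
    """

    read_id: str
    strand: str
    exon_id: int
    insert: str
    path: tuple[tuple[str, int], ...]
    edit_distance: int
    identity: float
    unalignable: bool


def _aligner() -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = ALIGN_SCORES
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_GLOBAL_ALIGNER = _aligner()


@functools.lru_cache(maxsize=100_000)
def _analyze(insert: str, amplicon: AmpliconDef) -> tuple:
    """Core cached analysis of one distinct insert sequence.

    Returns ``(path, edit_distance, identity, observations)`` where
    ``observations`` is a tuple of ``(VariantKey, in_homopolymer)``.
    """
    ref = amplicon.insert
    if insert == ref:
        return ((("=", len(ref)),), 0, 1.0, ())
    alignment = _GLOBAL_ALIGNER.align(ref, insert)[0]
    ref_blocks, query_blocks = alignment.aligned
    ops: list[tuple[str, int]] = []
    raw: list[tuple[int, str, str]] = []  # (ref_pos, ref_allele, alt_allele)
    matches = 0
    columns = 0

    def push(op: str, length: int) -> None:
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    prev_t, prev_q = 0, 0
    for (ts, te), (qs, qe) in zip(ref_blocks.tolist(), query_blocks.tolist()):
        if ts > prev_t and qs > prev_q:  # unaligned stretch on both: delins
            raw.append((prev_t, ref[prev_t:ts], insert[prev_q:qs]))
            push("D", ts - prev_t)
            push("I", qs - prev_q)
            columns += (ts - prev_t) + (qs - prev_q)
        elif ts > prev_t:
            raw.append((prev_t, ref[prev_t:ts], ""))
            push("D", ts - prev_t)
            columns += ts - prev_t
        elif qs > prev_q:
            raw.append((ts, "", insert[prev_q:qs]))
            push("I", qs - prev_q)
            columns += qs - prev_q
        run_start = ts
        for i in range(te - ts):
            if ref[ts + i] == insert[qs + i]:
                matches += 1
            else:
                push("=", ts + i - run_start)
                push("X", 1)
                run_start = ts + i + 1
                raw.append((ts + i, ref[ts + i], insert[qs + i]))
        push("=", te - run_start)
        columns += te - ts
        prev_t, prev_q = te, qe
    if prev_t < len(ref) or prev_q < len(insert):
        if prev_t < len(ref) and prev_q < len(insert):
            raw.append((prev_t, ref[prev_t:], insert[prev_q:]))
        elif prev_t < len(ref):
            raw.append((prev_t, ref[prev_t:], ""))
        else:
            raw.append((len(ref), "", insert[prev_q:]))
        push("D", len(ref) - prev_t)
        push("I", len(insert) - prev_q)
        columns += (len(ref) - prev_t) + (len(insert) - prev_q)
    identity = matches / columns if columns else 0.0
    edit_distance = sum(max(len(r), len(a)) for _, r, a in raw)
    observations = _normalize_edits(raw, amplicon)
    return (tuple(ops), edit_distance, identity, observations)


def _event_complexity(ref_seg: str, alt_seg: str) -> int:
    """Length of the parsimony-trimmed representation of one event."""
    while ref_seg and alt_seg and ref_seg[-1] == alt_seg[-1]:
        ref_seg, alt_seg = ref_seg[:-1], alt_seg[:-1]
    while ref_seg and alt_seg and ref_seg[0] == alt_seg[0]:
        ref_seg, alt_seg = ref_seg[1:], alt_seg[1:]
    return len(ref_seg) + len(alt_seg)


def _consolidate_delins(events: list[tuple[int, int, str]], ref: str
                        ) -> list[tuple[int, int, str]]:
    """Fuse a length-changing event with a neighbour when one contiguous
    deletion-insertion describes the pair at least as parsimoniously.

    Affine-gap alignment of a single biological delins can leave accidental
    matching columns between the gap and the substituted bases; fusing by
    minimum description recovers the single event while never joining
    genuinely independent, distant edits (whose fused description is longer).
    """
    changed = True
    while changed and len(events) > 1:
        changed = False
        out = [events[0]]
        for start, end, alt in events[1:]:
            ps, pe, palt = out[-1]
            indel_involved = (pe - ps != len(palt)) or (end - start != len(alt))
            fused_alt = palt + ref[pe:start] + alt
            if indel_involved and _event_complexity(ref[ps:end], fused_alt) <= (
                _event_complexity(ref[ps:pe], palt)
                + _event_complexity(ref[start:end], alt)
            ):
                out[-1] = (ps, end, fused_alt)
                changed = True
            else:
                out.append((start, end, alt))
        events = out
    return events


def _normalize_edits(raw: list[tuple[int, str, str]], amplicon: AmpliconDef
                     ) -> tuple[tuple[VariantKey, bool], ...]:
    """Merge nearby edits, left-align, and flag homopolymer contact.

    Input edits are in insert coordinates; output keys are CDS coordinates.
    """
    if not raw:
        return ()
    raw = sorted(raw)
    # merge edits whose reference spans are within MERGE_WINDOW bases
    merged: list[tuple[int, int, str]] = []  # (ref_start, ref_end, alt)
    ref = amplicon.insert
    for pos, r, a in raw:
        start, end = pos, pos + len(r)
        if merged and start - merged[-1][1] <= MERGE_WINDOW:
            ps, pe, palt = merged[-1]
            merged[-1] = (ps, end, palt + ref[pe:start] + a)
        else:
            merged.append((start, end, a))
    merged = _consolidate_delins(merged, ref)
    out = []
    offset = amplicon.insert_offset  # insert -> full reference coordinates
    runs = amplicon.homopolymer_runs(HOMOPOLYMER_MIN_RUN)
    for start, end, alt in merged:
        cds_start = amplicon.cds_coord(start + offset)
        cds_end = amplicon.cds_coord(end + offset - 1)
        if end == start:  # pure insertion: key names the base before
            cds_start = cds_end = amplicon.cds_coord(start + offset - 1)
        key = refdata.normalize_variant(
            amplicon, VariantKey(cds_start, cds_end, ref[start:end], alt)
        )
        # homopolymer contact, computed on the reference from the
        # normalized placement, expanded one base either side (adjacency)
        k_start = amplicon.ref_index(key.cds_start)
        k_end = k_start + max(len(key.ref), 1)
        if key.ref == "":
            k_end = k_start + 2  # insertion after k_start: touches both sides
        touch = any(rs < k_end + 1 and re > k_start - 1 for rs, re in runs)
        out.append((key, touch))
    return tuple(out)


def align_read(
    insert: str,
    amplicon: AmpliconDef,
    strand: str,
    read_id: str = "read",
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> AlignedRead:
    """Globally align one read insert to the amplicon insert.

    Reverse-strand inserts are reverse-complemented first.  Alignments with
    identity below ``identity_floor`` are flagged unalignable and excluded
    from tallies downstream.
    """
    if not insert:
        raise ValueError("empty insert")
    if strand == "reverse":
        insert = revcomp(insert)
    elif strand != "forward":
        raise ValueError(f"unknown strand {strand!r}")
    path, dist, identity, _ = _analyze(insert.upper(), amplicon)
    return AlignedRead(
        read_id=read_id,
        strand=strand,
        exon_id=amplicon.exon_id,
        insert=insert.upper(),
        path=path,
        edit_distance=dist,
        identity=identity,
        unalignable=identity < identity_floor,
    )


def extract_observations(aligned: AlignedRead, amplicon: AmpliconDef
                         ) -> list[Observation]:
    """Normalized per-read variant observations (empty for unalignable or
    zero-edit reads)."""
    if aligned.unalignable:
        return []
    _, _, _, obs = _analyze(aligned.insert, amplicon)
    return [
        Observation(aligned.read_id, aligned.strand, key, touch)
        for key, touch in obs
    ]


def name_variant(variant_key: VariantKey, amplicon: AmpliconDef) -> tuple[str, str]:
    """HGVS-style c. string and conventional protein name for a key.

    Frame-breaking events get a protein name marked ``fs``.
    """
    lo = amplicon.cds_coord(0)
    hi = amplicon.cds_coord(len(amplicon.reference_seq) - 1)
    if not (lo <= variant_key.cds_start <= hi):
        raise ValueError(f"variant {variant_key} outside exon {amplicon.exon_id} amplicon")
    cds = refdata.cds_change_string(variant_key)
    protein, _ = refdata.protein_change_for(amplicon, variant_key)
    return cds, protein


def write_sam(path: str | Path, amplicons: Sequence[AmpliconDef],
              aligned: Sequence[tuple[str, AlignedRead]]) -> None:
    """Write aligned reads as SAM (one reference sequence per amplicon).

    ``aligned`` holds ``(sample_id, AlignedRead)`` pairs; reads map at the
    insert start (just past the forward primer).
    """
    import pysam

    by_exon = {a.exon_id: a for a in amplicons}
    names = {a.exon_id: f"EGFR_ex{a.exon_id}_amplicon" for a in amplicons}
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": names[e], "LN": len(by_exon[e].reference_seq)}
            for e in sorted(by_exon)
        ],
    }
    op_to_cigar = {"=": 7, "X": 8, "I": 1, "D": 2}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for sample_id, ar in aligned:
            if ar.unalignable:
                continue
            amp = by_exon[ar.exon_id]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = ar.read_id
            seg.query_sequence = ar.insert
            seg.flag = 16 if ar.strand == "reverse" else 0
            seg.reference_id = sorted(by_exon).index(ar.exon_id)
            seg.reference_start = amp.insert_offset
            seg.mapping_quality = 60
            seg.cigartuples = [(op_to_cigar[op], ln) for op, ln in ar.path if ln > 0]
            seg.set_tag("RG", sample_id, "Z")
            seg.set_tag("NM", ar.edit_distance, "i")
            out.write(seg)
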