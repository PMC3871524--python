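"""Reference data for the EGFR exon 18-21 amplicon panel.

The panel holds one amplicon per EGFR tyrosine-kinase-domain exon (18, 19,
20, 21), each defined by the PCR primer pair, the primer-to-primer reference
sequence and the coding-coordinate offset that maps reference positions to
HGVS-style c. numbers, plus the catalog of known EGFR mutations used to
annotate calls with their predicted role for tyrosine-kinase-inhibitor (TKI)
treatment.

Reference sequences
-------------------
The bundled references are *synthetic stand-ins*, not the human genomic
sequence: each amplicon carries the published primer pair at its ends, has
the published amplicon length, and encodes the canonical EGFR protein
residue (with the canonical codon, where coordinate arithmetic depends on
it) at every hotspot position the panel is meant to interrogate -- G719,
the exon 19 deletion region K745..D761 (true nucleotides, so that deletion
left-alignment behaves as on the real gene), P772, T785, Q787, T790, F795,
D807, R831, V845 and the DFG..L858 activation-loop motif.  Filler codons
between landmarks are synthetic.  Deliberate homopolymer runs (four
adenines) are placed in each amplicon so that pyrosequencing-style
homopolymer noise has somewhere realistic to land.

Coordinates
-----------
CDS coordinates are 1-based c.-numbers with codon N spanning
c.(3N-2)..c.(3N); internal reference offsets are 0-based.  Some of the
older EGFR literature numbers the Q787Q polymorphism "c.2470 G>A"; that
legacy transcript numbering is offset +109 from standard CDS numbering
(standard c.2361), see :data:`LEGACY_TRANSCRIPT_OFFSET`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio.Seq import Seq

__all__ = [
    "AmpliconDef",
    "MutationCatalogEntry",
    "TkiRole",
    "VariantKey",
    "EXON_CODON_RANGES",
    "LEGACY_TRANSCRIPT_OFFSET",
    "Q787Q_SITE_CDS",
    "build_reference_bundle",
    "write_reference_bundle",
    "load_amplicons",
    "load_catalog",
    "save_catalog",
    "load_mid_inventory",
    "annotate",
    "annotate_cds",
    "cds_change_string",
    "protein_change_for",
    "normalize_variant",
    "parse_cds_change",
    "homopolymer_runs",
    "revcomp",
    "translate",
]


# --------------------------------------------------------------------------
# small sequence helpers

def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string (standard code, '*' for stop)."""
    return str(Seq(seq).translate())


def homopolymer_runs(seq: str, min_len: int = 4) -> tuple[tuple[int, int], ...]:
    """Maximal single-nucleotide runs of length >= min_len, as 0-based
    half-open (start, end) intervals."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return tuple(runs)


# --------------------------------------------------------------------------
# variant keys

class VariantKey(NamedTuple):
    """Normalized description of one nucleotide variant in CDS coordinates.

    ``cds_start``/``cds_end`` are inclusive 1-based c. positions of the
    replaced reference bases; ``ref`` is the replaced reference allele and
    ``alt`` the replacement.  A pure insertion has ``ref == ""`` and
    ``cds_start == cds_end`` naming the base *after* which the insertion
    occurs.  Keys are stored left-aligned and parsimony-reduced.
    """

    cds_start: int
    cds_end: int
    ref: str
    alt: str

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def cds_change_string(key: VariantKey) -> str:
    """HGVS-style c. string for a variant key."""
    s, e, ref, alt = key
    if len(ref) == 1 and len(alt) == 1:
        return f"c.{s}{ref}>{alt}"
    if ref and not alt:
        return f"c.{s}del" if s == e else f"c.{s}_{e}del"
    if alt and not ref:
        return f"c.{s}_{s + 1}ins{alt}"
    return f"c.{s}_{e}delins{alt}"


_CDS_RE = {
    "snv": re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$"),
    "del": re.compile(r"^c\.(\d+)(?:_(\d+))?del$"),
    "ins": re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$"),
    "delins": re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$"),
}


def parse_cds_change(text: str, amplicon: "AmpliconDef") -> VariantKey:
    """Parse a c. notation string into a (non-normalized) VariantKey, filling
    deleted reference alleles from the amplicon sequence."""
    text = text.strip()
    m = _CDS_RE["snv"].match(text)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        have = amplicon.base_at_cds(pos)
        if have != ref:
            raise ValueError(f"{text}: reference base at c.{pos} is {have}, not {ref}")
        return VariantKey(pos, pos, ref, alt)
    m = _CDS_RE["del"].match(text)
    if m:
        s = int(m.group(1))
        e = int(m.group(2)) if m.group(2) else s
        return VariantKey(s, e, amplicon.cds_slice(s, e), "")
    m = _CDS_RE["ins"].match(text)
    if m:
        s = int(m.group(1))
        return VariantKey(s, s, "", m.group(3))
    m = _CDS_RE["delins"].match(text)
    if m:
        s = int(m.group(1))
        e = int(m.group(2)) if m.group(2) else s
        return VariantKey(s, e, amplicon.cds_slice(s, e), m.group(3))
    raise ValueError(f"unrecognised cds change: {text!r}")


# --------------------------------------------------------------------------
# amplicon definitions

@dataclass(frozen=True)
class AmpliconDef:
    """One target region (EGFR exon) of the panel.

    ``reference_seq`` is the full primer-to-primer amplicon: the forward
    primer, a non-coding pad, the coding region (codons ``codon_start`` ..
    ``codon_end``), another pad, and the reverse complement of the reverse
    primer.  ``cds_offset`` maps 0-based reference indices to 1-based c.
    coordinates: ``c = index + cds_offset`` (pads and primers receive
    extrapolated coordinates; only the coding region carries meaning).
    """

    exon_id: int
    forward_primer: str
    reverse_primer: str
    reference_seq: str
    cds_offset: int
    expected_length_bp: int
    codon_start: int
    codon_end: int

    # -- coordinate mapping ------------------------------------------------
    def ref_index(self, cds: int) -> int:
        return cds - self.cds_offset

    def cds_coord(self, index: int) -> int:
        return index + self.cds_offset

    def base_at_cds(self, cds: int) -> str:
        return self.reference_seq[self.ref_index(cds)]

    def cds_slice(self, cds_start: int, cds_end: int) -> str:
        """Reference bases for the inclusive c. range."""
        return self.reference_seq[self.ref_index(cds_start): self.ref_index(cds_end) + 1]

    # -- derived regions ---------------------------------------------------
    @property
    def insert_offset(self) -> int:
        return len(self.forward_primer)

    @property
    def insert(self) -> str:
        """Reference between (and excluding) the primers."""
        return self.reference_seq[len(self.forward_primer): len(self.reference_seq) - len(self.reverse_primer)]

    @property
    def coding_cds_range(self) -> tuple[int, int]:
        """Inclusive c. range covered by the coding region."""
        return 3 * self.codon_start - 2, 3 * self.codon_end

    @property
    def coding_seq(self) -> str:
        lo, hi = self.coding_cds_range
        return self.cds_slice(lo, hi)

    def codon(self, n: int) -> str:
        if not self.codon_start <= n <= self.codon_end:
            raise ValueError(f"codon {n} outside exon {self.exon_id} amplicon")
        return self.cds_slice(3 * n - 2, 3 * n)

    def residue(self, n: int) -> str:
        return translate(self.codon(n))

    def homopolymer_runs(self, min_len: int = 4) -> tuple[tuple[int, int], ...]:
        """Runs on the full reference, 0-based reference intervals."""
        return homopolymer_runs(self.reference_seq, min_len)

    def insert_homopolymer_runs(self, min_len: int = 4) -> tuple[tuple[int, int], ...]:
        """Runs lying fully inside the insert, in insert coordinates."""
        off = self.insert_offset
        hi = len(self.reference_seq) - len(self.reverse_primer)
        return tuple(
            (s - off, e - off)
            for s, e in self.homopolymer_runs(min_len)
            if s >= off and e <= hi
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        seq = self.reference_seq
        if len(seq) != self.expected_length_bp:
            raise ValueError(
                f"exon {self.exon_id}: reference length {len(seq)} != expected {self.expected_length_bp}"
            )
        if not seq.startswith(self.forward_primer):
            raise ValueError(f"exon {self.exon_id}: forward primer not at reference start")
        if not seq.endswith(revcomp(self.reverse_primer)):
            raise ValueError(f"exon {self.exon_id}: reverse primer (revcomp) not at reference end")
        lo, hi = self.coding_cds_range
        if self.ref_index(lo) < len(self.forward_primer) or self.ref_index(hi) >= len(seq) - len(self.reverse_primer):
            raise ValueError(f"exon {self.exon_id}: coding region extends into primers")
        if set(seq) - set("ACGT"):
            raise ValueError(f"exon {self.exon_id}: non-ACGT characters in reference")


# --------------------------------------------------------------------------
# synthetic bundle construction

# Published primer pairs and amplicon lengths for EGFR exons 18-21
# (dideoxy-sequencing primer set; upper-cased).
_PRIMERS = {
    18: ("CATGTCTGGCACTGCTTTCC", "AGGGACCTTACCTTATACACC", 184),
    19: ("AGCATGTGGCACCATCTCAC", "ATGAGAAAAGGTGGGCCTGA", 182),
    20: ("AGCCACACTGACGTGCCTCT", "CCTTATCTCCCCTCCCCGTA", 208),
    21: ("TGCAGAGCTTCTTCCCATGA", "GCATGTGTTAAACAATACAGC", 196),
}

# Codon span modelled by each amplicon (kinase-domain coordinates including
# the signal peptide, the numbering conventionally used for EGFR: L858R etc).
EXON_CODON_RANGES = {18: (688, 728), 19: (729, 761), 20: (770, 810), 21: (825, 865)}

# Codon ranges of the EGFR exons, used to assign a mutation to its exon.
_EXON_FULL_CODON_RANGES = {18: (688, 728), 19: (729, 761), 20: (762, 823), 21: (824, 875)}

#: Offset between the legacy EGFR transcript numbering used by some older
#: reports (which places the Q787Q polymorphism at "2470") and standard CDS
#: numbering (c.2361).
LEGACY_TRANSCRIPT_OFFSET = 109

#: Standard-numbering c. position of the third base of codon 787 (CAG); the
#: G>A polymorphism here is the synonymous Q787Q landmark used for the
#: dilution-series sensitivity experiments.
Q787Q_SITE_CDS = 2361

# Canonical EGFR codons at landmark positions.  The exon 19 block 745-761 is
# the true gene sequence (so deletion alignment ambiguity matches the real
# locus); codon pairs like (700, 701) -> CAA+AAT deliberately create a
# 4-adenine homopolymer run.  Everything not listed here is synthetic filler.
_LANDMARK_CODONS: dict[int, str] = {
    # exon 18
    690: "ATG", 691: "CCT",  # P691 (preceding codon fixed to avoid a C run)
    700: "CAA", 701: "AAT",  # synthetic AAAA run
    708: "AAA", 709: "GAA",  # K708, E709
    718: "CTG", 719: "GGC", 720: "TCA", 721: "GGG",  # L-G719-S-G721 (P-loop)
    # exon 19 (true sequence K745..D761)
    733: "CAA", 734: "AAT",  # synthetic AAAA run
    745: "AAG", 746: "GAA", 747: "TTA", 748: "AGA", 749: "GAA", 750: "GCA",
    751: "ACA", 752: "TCT", 753: "CCG", 754: "AAA", 755: "GCC", 756: "AAC",
    757: "AAG", 758: "GAA", 759: "ATC", 760: "CTC", 761: "GAT",
    # exon 20
    772: "CCT",  # P772
    775: "CAA", 776: "AAT",  # synthetic AAAA run
    785: "ACT",  # T785
    787: "CAG", 788: "CTG", 789: "ATC", 790: "ACG", 791: "CAG", 792: "CTC",
    793: "ATG",  # Q787 .. T790 (gatekeeper) .. M793
    795: "TTC",  # F795
    807: "GAC",  # D807
    # exon 21
    831: "CGC",  # R831
    835: "CAA", 836: "AAT",  # synthetic AAAA run
    845: "GTG",  # V845
    855: "GAC", 856: "TTT", 857: "GGC", 858: "CTG", 859: "GCC",  # DFG-L858-A
}

# Filler codons cycle; none ends in A and no inter-codon junction in the
# cycle creates a homopolymer run of length >= 3.
_FILLER = ("GAT", "CTG", "ACC", "GTC", "TGC", "CAT", "TCG", "GCT")

_PAD_PATTERN = "TCAGG"

#: Note recorded with the bundle: the sequences are synthetic stand-ins.
TRANSCRIPT_NOTE = (
    "synthetic reference; coordinates follow standard EGFR CDS numbering "
    "(codon N at c.3N-2..3N, signal peptide included); landmark codons match "
    "the canonical EGFR protein, filler is synthetic"
)


def _pad(n: int) -> str:
    return (_PAD_PATTERN * (n // len(_PAD_PATTERN) + 1))[:n]


def _codon_for(n: int) -> str:
    return _LANDMARK_CODONS.get(n, _FILLER[n % len(_FILLER)])


def build_reference_bundle() -> list[AmpliconDef]:
    """Construct the four synthetic amplicon definitions in code.

    The packaged FASTA/TSV bundle is written from this function; loading the
    bundle and rebuilding it give identical definitions.
    """
    amplicons = []
    for exon in (18, 19, 20, 21):
        fwd, rev, length = _PRIMERS[exon]
        c0, c1 = EXON_CODON_RANGES[exon]
        coding = "".join(_codon_for(n) for n in range(c0, c1 + 1))
        pad_total = length - len(fwd) - len(rev) - len(coding)
        if pad_total < 2:
            raise AssertionError(f"exon {exon}: coding region too long for amplicon")
        left = pad_total // 2
        seq = fwd + _pad(left) + coding + _pad(pad_total - left) + revcomp(rev)
        coding_start = len(fwd) + left
        amp = AmpliconDef(
            exon_id=exon,
            forward_primer=fwd,
            reverse_primer=rev,
            reference_seq=seq,
            cds_offset=3 * c0 - 2 - coding_start,
            expected_length_bp=length,
            codon_start=c0,
            codon_end=c1,
        )
        amp.validate()
        # every deliberate AAAA run must exist inside the insert, and no
        # accidental run may have appeared in filler/pad/junctions
        insert_runs = amp.insert_homopolymer_runs()
        expected = sum(
            1 for n in _LANDMARK_CODONS
            if c0 <= n <= c1 and _LANDMARK_CODONS[n] == "CAA"
            and _LANDMARK_CODONS.get(n + 1) == "AAT"
        )
        if len(insert_runs) != expected:
            raise AssertionError(
                f"exon {exon}: expected {expected} insert homopolymer runs, found {insert_runs}"
            )
        amplicons.append(amp)
    return amplicons


_BUNDLE_SIDE_COLUMNS = (
    "exon", "forward_primer", "reverse_primer", "expected_length_bp",
    "cds_offset", "codon_start", "codon_end", "note",
)


def write_reference_bundle(directory: str | Path) -> tuple[Path, Path]:
    """Write the synthetic bundle as FASTA + sidecar coordinate TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "amplicons.fasta"
    side = directory / "amplicons.tsv"
    amps = build_reference_bundle()
    with fasta.open("w") as fh:
        for amp in amps:
            fh.write(f">EGFR_ex{amp.exon_id}_amplicon synthetic\n{amp.reference_seq}\n")
    with side.open("w") as fh:
        fh.write("\t".join(_BUNDLE_SIDE_COLUMNS) + "\n")
        for amp in amps:
            fh.write(
                f"{amp.exon_id}\t{amp.forward_primer}\t{amp.reverse_primer}\t"
                f"{amp.expected_length_bp}\t{amp.cds_offset}\t{amp.codon_start}\t"
                f"{amp.codon_end}\t{TRANSCRIPT_NOTE}\n"
            )
    return fasta, side


def _data_path(*parts: str) -> Path:
    return Path(resources.files("amplicall").joinpath("data", *parts))  # type: ignore[arg-type]


def load_amplicons(directory: str | Path | None = None) -> list[AmpliconDef]:
    """Load and validate the amplicon bundle (FASTA + sidecar TSV).

    Raises ``ValueError`` naming the exon on a missing record or a length
    mismatch against the expected amplicon length.
    """
    from Bio import SeqIO

    directory = Path(directory) if directory is not None else _data_path()
    fasta = directory / "amplicons.fasta"
    side = directory / "amplicons.tsv"
    seqs: dict[int, str] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        m = re.match(r"EGFR_ex(\d+)_amplicon", rec.id)
        if m:
            seqs[int(m.group(1))] = str(rec.seq).upper()
    amplicons = []
    with side.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            exon = int(row["exon"])
            if exon not in seqs:
                raise ValueError(f"reference bundle is missing exon {exon}")
            amp = AmpliconDef(
                exon_id=exon,
                forward_primer=row["forward_primer"].upper(),
                reverse_primer=row["reverse_primer"].upper(),
                reference_seq=seqs[exon],
                cds_offset=int(row["cds_offset"]),
                expected_length_bp=int(row["expected_length_bp"]),
                codon_start=int(row["codon_start"]),
                codon_end=int(row["codon_end"]),
            )
            amp.validate()
            amplicons.append(amp)
    for exon in (18, 19, 20, 21):
        if exon not in {a.exon_id for a in amplicons}:
            raise ValueError(f"reference bundle is missing exon {exon}")
    return sorted(amplicons, key=lambda a: a.exon_id)


def amplicon_for_exon(amplicons: Sequence[AmpliconDef], exon_id: int) -> AmpliconDef:
    for amp in amplicons:
        if amp.exon_id == exon_id:
            return amp
    raise ValueError(f"no amplicon for exon {exon_id}")


def amplicon_for_cds(amplicons: Sequence[AmpliconDef], cds: int) -> AmpliconDef:
    for amp in amplicons:
        lo, hi = amp.coding_cds_range
        if lo <= cds <= hi:
            return amp
    raise ValueError(f"c.{cds} is outside the covered exon 18-21 panel")


# --------------------------------------------------------------------------
# variant normalization and naming

def normalize_variant(amplicon: AmpliconDef, key: VariantKey) -> VariantKey:
    """Parsimony-reduce and left-align a variant key against the reference.

    Pure insertions/deletions in repetitive context are shifted to their
    leftmost alignment-equivalent position (VCF/HGVS-3' disagreements are
    resolved leftward, deterministically).
    """
    s, e, ref, alt = key
    # trim common suffix then prefix
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        e -= 1
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        s += 1
    seq = amplicon.reference_seq
    if ref and not alt:  # deletion: shift left while preceding base equals last deleted
        i = amplicon.ref_index(s)
        k = len(ref)
        while i > 0 and seq[i - 1] == seq[i + k - 1]:
            i -= 1
        s = amplicon.cds_coord(i)
        e = s + k - 1
        ref = seq[i: i + k]
    elif alt and not ref:  # insertion: shift left while preceding base equals last inserted
        i = amplicon.ref_index(s)  # insertion after reference index i (1-based cds of base before)
        while i > 0 and seq[i] == alt[-1]:
            alt = alt[-1] + alt[:-1]
            i -= 1
        s = e = amplicon.cds_coord(i)
    if not ref and not alt:
        raise ValueError("empty variant")
    return VariantKey(s, e, ref, alt)


def protein_change_for(amplicon: AmpliconDef, key: VariantKey) -> tuple[str, bool]:
    """Protein-level name for a variant, in the conventional EGFR reporting
    style ("L858R", "del E746-A750", "del L747-A750 insP", "Q787Q").

    Returns ``(name, is_frameshift)``.  Variants outside the coding region
    are named ``"non-coding"``.
    """
    lo, hi = amplicon.coding_cds_range
    s, e, ref, alt = key
    if ref == "":  # insertion after position s
        inside = lo <= s < hi
    else:
        inside = s >= lo and e <= hi
    if not inside:
        return "non-coding", False
    coding = amplicon.coding_seq
    i0 = s - lo
    if ref == "":
        alt_coding = coding[: i0 + 1] + alt + coding[i0 + 1:]
    else:
        alt_coding = coding[:i0] + alt + coding[i0 + len(ref):]
    if (len(alt) - len(ref)) % 3 != 0:
        m = amplicon.codon_start + i0 // 3
        return f"{translate(amplicon.codon(m))}{m}fs", True
    ref_aa = translate(coding)
    alt_aa = translate(alt_coding[: len(alt_coding) - len(alt_coding) % 3])
    if ref_aa == alt_aa:  # synonymous
        m = amplicon.codon_start + i0 // 3
        x = ref_aa[i0 // 3]
        return f"{x}{m}{x}", False
    # trim common prefix/suffix at residue level
    p = 0
    while p < min(len(ref_aa), len(alt_aa)) and ref_aa[p] == alt_aa[p]:
        p += 1
    q = 0
    while (
        q < min(len(ref_aa), len(alt_aa)) - p
        and ref_aa[len(ref_aa) - 1 - q] == alt_aa[len(alt_aa) - 1 - q]
    ):
        q += 1
    ref_seg = ref_aa[p: len(ref_aa) - q]
    alt_seg = alt_aa[p: len(alt_aa) - q]
    a = amplicon.codon_start + p
    b = a + len(ref_seg) - 1
    if len(ref_seg) == 1 and len(alt_seg) == 1:
        return f"{ref_seg}{a}{alt_seg}", False
    if ref_seg and not alt_seg:
        if len(ref_seg) == 1:
            return f"del {ref_seg}{a}", False
        return f"del {ref_seg[0]}{a}-{ref_seg[-1]}{b}", False
    if alt_seg and not ref_seg:
        prev = ref_aa[p - 1] if p else "?"
        return f"{prev}{amplicon.codon_start + p - 1}_{ref_aa[p]}{a}ins{alt_seg}", False
    if len(ref_seg) == 1:
        return f"del {ref_seg}{a} ins{alt_seg}", False
    return f"del {ref_seg[0]}{a}-{ref_seg[-1]}{b} ins{alt_seg}", False


# --------------------------------------------------------------------------
# mutation catalog

class TkiRole(str, enum.Enum):
    """Predicted role of a mutation for TKI treatment."""

    RESPONSE = "response"
    RESISTANCE = "resistance"
    PUTATIVE_RESPONSE = "putative_response"
    UNDEFINED = "undefined"
    NOVEL = "novel"


@dataclass(frozen=True)
class MutationCatalogEntry:
    protein_change: str
    exon_id: int
    cds_change: str
    tki_role: TkiRole


#: protein name used for the exon 19 in-frame deletion class.
EXON19_DELETION_CLASS = "Exon 19 deletion"

_EX19_DEL_RE = re.compile(r"^del [A-Z]\d+(-[A-Z]\d+)?$")
_SYNONYMOUS_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


def default_catalog() -> list[MutationCatalogEntry]:
    """The known-mutation catalog observed in the validation series."""
    rows = [
        ("G719A", 18, "c.2156G>C", TkiRole.RESPONSE),
        (EXON19_DELETION_CLASS, 19, "-", TkiRole.RESPONSE),
        ("L858R", 21, "c.2573T>G", TkiRole.RESPONSE),
        ("P772S", 20, "c.2314C>T", TkiRole.PUTATIVE_RESPONSE),
        ("T790M", 20, "c.2369C>T", TkiRole.RESISTANCE),
        ("R831H", 21, "c.2492G>A", TkiRole.RESISTANCE),
        ("F795S", 20, "c.2384T>C", TkiRole.UNDEFINED),
        ("T785I", 20, "c.2354C>T", TkiRole.UNDEFINED),
        ("V845M", 21, "c.2533G>A", TkiRole.UNDEFINED),
        ("P691T", 18, "c.2071C>A", TkiRole.NOVEL),
        ("K708N", 18, "c.2124A>T", TkiRole.NOVEL),
        ("G721W", 18, "c.2161G>T", TkiRole.NOVEL),
        ("S752F", 19, "c.2255C>T", TkiRole.NOVEL),
        ("D807G", 20, "c.2420A>G", TkiRole.NOVEL),
    ]
    return [MutationCatalogEntry(p, x, c, r) for p, x, c, r in rows]


def save_catalog(entries: Iterable[MutationCatalogEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein_change\texon\tcds_change\ttki_role\n")
        for e in entries:
            fh.write(f"{e.protein_change}\t{e.exon_id}\t{e.cds_change}\t{e.tki_role.value}\n")


def load_catalog(path: str | Path | None = None) -> list[MutationCatalogEntry]:
    path = Path(path) if path is not None else _data_path("mutation_catalog.tsv")
    entries = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            entries.append(
                MutationCatalogEntry(
                    protein_change=row["protein_change"],
                    exon_id=int(row["exon"]),
                    cds_change=row["cds_change"],
                    tki_role=TkiRole(row["tki_role"]),
                )
            )
    return entries


def _exon_for_codon(codon: int) -> int | None:
    for exon, (lo, hi) in _EXON_FULL_CODON_RANGES.items():
        if lo <= codon <= hi:
            return exon
    return None


def annotate(
    protein_change: str,
    exon_id: int | None = None,
    catalog: Sequence[MutationCatalogEntry] | None = None,
) -> MutationCatalogEntry:
    """Annotate a protein-level change against the mutation catalog.

    Exact catalog matches return the catalog entry; in-frame exon 19
    deletions map to the exon-19-deletion class; synonymous changes are
    annotated with an undefined TKI role; anything else is returned as a
    novel entry.
    """
    catalog = catalog if catalog is not None else load_catalog()
    for entry in catalog:
        if entry.protein_change == protein_change:
            return entry
    m = _SYNONYMOUS_RE.match(protein_change)
    if m and m.group(1) == m.group(3):
        codon = int(m.group(2))
        exon = exon_id if exon_id is not None else _exon_for_codon(codon)
        return MutationCatalogEntry(protein_change, exon or 0, "-", TkiRole.UNDEFINED)
    if exon_id == 19 and _EX19_DEL_RE.match(protein_change):
        for entry in catalog:
            if entry.protein_change == EXON19_DELETION_CLASS:
                return entry
    return MutationCatalogEntry(protein_change, exon_id or 0, "-", TkiRole.NOVEL)


def annotate_cds(
    cds_change: str,
    amplicons: Sequence[AmpliconDef] | None = None,
    catalog: Sequence[MutationCatalogEntry] | None = None,
) -> MutationCatalogEntry:
    """Annotate a c.-notation change: locate its amplicon, derive the protein
    name by re-translation and look it up in the catalog.

    Raises ``ValueError`` for positions outside the covered exons.
    """
    amplicons = amplicons if amplicons is not None else load_amplicons()
    m = re.match(r"^c\.(\d+)", cds_change.strip())
    if not m:
        raise ValueError(f"unrecognised cds change: {cds_change!r}")
    amp = amplicon_for_cds(amplicons, int(m.group(1)))
    key = normalize_variant(amp, parse_cds_change(cds_change, amp))
    protein, _ = protein_change_for(amp, key)
    return annotate(protein, amp.exon_id, catalog)


# --------------------------------------------------------------------------
# MID inventory

#: Example 10-nt multiplex identifier tags (distinct, exact-match barcodes).
DEFAULT_MID_INVENTORY = (
    "ACGAGTGCGT", "ACGCTCGACA", "AGACGCACTC", "AGCACTGTAG",
    "ATCAGACACG", "ATATCGCGAG", "CGTGTCTCTA", "CTCGCGTGTC",
    "TCTCTATGCG", "TGATACGTCT", "CATAGTAGTG", "CGAGAGATAC",
    "GTCACGTACT", "GATCGTGACA", "TACGAGTATG", "TAGCTGCAGT",
)


def load_mid_inventory(path: str | Path | None = None) -> list[str]:
    if path is None:
        path = _data_path("mid_inventory.tsv")
    tags = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tag = line.split("\t")[-1].upper()
            if tag == "TAG":  # column header
                continue
            tags.append(tag)
    if len(set(tags)) != len(tags):
        raise ValueError("MID inventory contains duplicate tags")
    for tag in tags:
        if len(tag) != 10 or set(tag) - set("ACGT"):
            raise ValueError(f"invalid MID tag {tag!r}")
    return tags
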