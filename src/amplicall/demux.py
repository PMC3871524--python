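"""Combinatorial MID-pair grid design and read demultiplexing.

A unique (forward MID, reverse MID) pair identifies each sample; the grid
scheme assigns pairs row-major over a small set of forward- and
reverse-tagged primers, so that f forward x r reverse tags cover f*r
samples (5 x 6 tags suffice for 30 samples in one run).  Matching is exact
on both 10-nt MIDs -- a single matching MID, or any mismatch, sends the
read to the unassigned pile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

from .refdata import AmpliconDef, revcomp
from .simulate import DEFAULT_SPACER

__all__ = [
    "MIDPair",
    "GridScheme",
    "ReadBin",
    "DemuxResult",
    "design_grid",
    "demultiplex",
    "read_fastq_tolerant",
    "write_grid",
    "load_grid",
    "write_demux_report",
]


class MIDPair(NamedTuple):
    forward_mid: str
    reverse_mid: str


def _check_mid(tag: str) -> str:
    tag = tag.upper()
    if len(tag) != 10 or set(tag) - set("ACGT"):
        raise ValueError(f"MID must be a 10-nt ACGT string, got {tag!r}")
    return tag


@dataclass(frozen=True)
class GridScheme:
    """Per-exon mapping from sample to MID pair.

    The same pair-to-sample layout is used on every exon (the amplicon
    primer, not the MID pair, distinguishes exons).
    """

    exons: tuple[int, ...]
    samples: tuple[str, ...]
    forward_mids: tuple[str, ...]
    reverse_mids: tuple[str, ...]
    assignments: dict = field(repr=False)  # {exon: {sample: MIDPair}}

    @property
    def n_forward(self) -> int:
        return len(self.forward_mids)

    @property
    def n_reverse(self) -> int:
        return len(self.reverse_mids)

    def pair_for(self, exon_id: int, sample_id: str) -> MIDPair:
        try:
            return self.assignments[exon_id][sample_id]
        except KeyError:
            raise KeyError(f"no MID pair for sample {sample_id!r} on exon {exon_id}") from None

    def sample_for(self, exon_id: int, pair: MIDPair) -> str | None:
        return self._pair_lookup().get((exon_id, pair))

    def _pair_lookup(self) -> dict:
        # built lazily; frozen dataclass, so cache on the dict object itself
        cache = getattr(self, "_lookup_cache", None)
        if cache is None:
            cache = {
                (exon, pair): sample
                for exon, table in self.assignments.items()
                for sample, pair in table.items()
            }
            object.__setattr__(self, "_lookup_cache", cache)
        return cache

    def validate(self) -> None:
        for exon, table in self.assignments.items():
            seen: dict[MIDPair, str] = {}
            for sample, pair in table.items():
                _check_mid(pair.forward_mid)
                _check_mid(pair.reverse_mid)
                if pair in seen:
                    raise ValueError(
                        f"exon {exon}: MID pair {pair} assigned to both "
                        f"{seen[pair]!r} and {sample!r}"
                    )
                seen[pair] = sample


def _minimal_grid_shape(n_samples: int) -> tuple[int, int]:
    """Smallest (f, r) with f*r >= n, minimizing f+r; ties broken toward the
    most balanced pair with f <= r."""
    best: tuple[int, int, int] | None = None  # (sum, -f, r)
    f = 1
    while True:
        r = -(-n_samples // f)  # ceil
        if r < f:
            break
        cand = (f + r, -f)
        if best is None or cand < best[:2]:
            best = (f + r, -f, r)
        f += 1
    assert best is not None
    return -best[1], best[2]


def design_grid(
    n_samples: int,
    mid_inventory: Sequence[str],
    sample_ids: Sequence[str] | None = None,
    exons: Sequence[int] = (18, 19, 20, 21),
) -> GridScheme:
    """Design the smallest combinatorial MID grid covering ``n_samples``.

    Chooses the minimal total number of tagged primers (n_forward +
    n_reverse with n_forward * n_reverse >= n_samples), takes forward and
    reverse tags from disjoint slices of the inventory and assigns pairs
    row-major: sample k -> (forward k // n_reverse, reverse k % n_reverse).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    inventory = [_check_mid(t) for t in mid_inventory]
    if len(set(inventory)) != len(inventory):
        raise ValueError("MID inventory contains duplicate tags")
    f, r = _minimal_grid_shape(n_samples)
    if f + r > len(inventory):
        raise ValueError(
            f"MID inventory too small: need {f} forward + {r} reverse = {f + r} "
            f"tags for {n_samples} samples, have {len(inventory)}"
        )
    fwd = tuple(inventory[:f])
    rev = tuple(inventory[f: f + r])
    if sample_ids is None:
        sample_ids = tuple(f"S{i + 1:02d}" for i in range(n_samples))
    elif len(sample_ids) != n_samples:
        raise ValueError("sample_ids length must equal n_samples")
    table = {
        sample: MIDPair(fwd[k // r], rev[k % r])
        for k, sample in enumerate(sample_ids)
    }
    grid = GridScheme(
        exons=tuple(exons),
        samples=tuple(sample_ids),
        forward_mids=fwd,
        reverse_mids=rev,
        assignments={exon: dict(table) for exon in exons},
    )
    grid.validate()
    return grid


def write_grid(grid: GridScheme, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("exon\tsample_id\tforward_mid\treverse_mid\n")
        for exon in grid.exons:
            for sample in grid.samples:
                pair = grid.pair_for(exon, sample)
                fh.write(f"{exon}\t{sample}\t{pair.forward_mid}\t{pair.reverse_mid}\n")


def load_grid(path: str | Path) -> GridScheme:
    assignments: dict[int, dict[str, MIDPair]] = {}
    samples: list[str] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            exon = int(row["exon"])
            pair = MIDPair(_check_mid(row["forward_mid"]), _check_mid(row["reverse_mid"]))
            assignments.setdefault(exon, {})[row["sample_id"]] = pair
            if row["sample_id"] not in samples:
                samples.append(row["sample_id"])
    fwd, rev = [], []
    for table in assignments.values():
        for pair in table.values():
            if pair.forward_mid not in fwd:
                fwd.append(pair.forward_mid)
            if pair.reverse_mid not in rev:
                rev.append(pair.reverse_mid)
    grid = GridScheme(
        exons=tuple(sorted(assignments)),
        samples=tuple(samples),
        forward_mids=tuple(fwd),
        reverse_mids=tuple(rev),
        assignments=assignments,
    )
    grid.validate()
    return grid


# --------------------------------------------------------------------------
# demultiplexing

@dataclass
class ReadBin:
    """Demultiplexed, strand-oriented reads for one (sample, exon) target."""

    sample_id: str
    exon_id: int
    reads: list[tuple[str, str, str]] = field(default_factory=list)
    # (read_id, insert sequence, strand in {"forward", "reverse"})

    @property
    def total_reads(self) -> int:
        return len(self.reads)


@dataclass
class DemuxResult:
    bins: dict  # {(sample_id, exon_id): ReadBin}
    unassigned: list  # [(read_id, reason)]
    n_reads: int
    n_corrupt: int

    @property
    def n_assigned(self) -> int:
        return sum(b.total_reads for b in self.bins.values())


def read_fastq_tolerant(path: str | Path) -> Iterator[tuple[str, str] | None]:
    """Yield (read_id, sequence) from a 4-line FASTQ; a malformed record
    yields ``None`` instead of aborting the stream (corrupt records are
    counted and reported downstream, never fatal)."""
    with Path(path).open() as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            head, seq, plus, qual = (s.rstrip("\n") for s in (head, seq, plus, qual))
            if (
                not head.startswith("@")
                or not plus.startswith("+")
                or len(seq) != len(qual)
                or set(seq.upper()) - set("ACGTN")
            ):
                yield None
                continue
            yield head[1:].split()[0], seq.upper()


def demultiplex(
    reads: str | Path | Iterable[tuple[str, str] | None],
    grid: GridScheme,
    amplicons: Sequence[AmpliconDef],
    spacer: str = DEFAULT_SPACER,
) -> DemuxResult:
    """Assign reads to (sample, exon) bins by exact dual-MID matching.

    Orientation is set by which end carries a known forward MID; the MID,
    spacer and primer sequences are trimmed and the stored insert is
    primer-free.  Reads failing any exact match land in ``unassigned`` with
    a reason.
    """
    grid.validate()
    if isinstance(reads, (str, Path)):
        reads = read_fastq_tolerant(reads)
    fwd_set = set(grid.forward_mids)
    rev_set = set(grid.reverse_mids)
    by_primer = {}
    for amp in amplicons:
        by_primer[amp.forward_primer] = amp
    primer_lens = sorted({len(a.forward_primer) for a in amplicons})
    ls = len(spacer)
    spacer_rc = revcomp(spacer)
    bins: dict[tuple[str, int], ReadBin] = {
        (sample, exon): ReadBin(sample, exon)
        for exon in grid.exons
        for sample in grid.samples
    }
    unassigned: list[tuple[str, str]] = []
    n_reads = 0
    n_corrupt = 0
    min_len = 2 * (10 + ls) + 20
    for item in reads:
        if item is None:
            n_corrupt += 1
            continue
        rid, seq = item
        n_reads += 1
        if len(seq) < min_len:
            unassigned.append((rid, "too_short"))
            continue
        head = seq[:10]
        if head in fwd_set:
            oriented, strand = seq, "forward"
        elif head in rev_set:
            oriented, strand = revcomp(seq), "reverse"
        else:
            unassigned.append((rid, "unknown_mid"))
            continue
        fm, rm = oriented[:10], revcomp(oriented[-10:])
        if fm not in fwd_set or rm not in rev_set:
            unassigned.append((rid, "unknown_mid"))
            continue
        if oriented[10:10 + ls] != spacer or oriented[-(10 + ls):-10] != spacer_rc:
            unassigned.append((rid, "spacer_mismatch"))
            continue
        core = oriented[10 + ls: len(oriented) - 10 - ls]
        amp = None
        for plen in primer_lens:
            amp = by_primer.get(core[:plen])
            if amp is not None:
                break
        if amp is None or not core.endswith(revcomp(amp.reverse_primer)):
            unassigned.append((rid, "primer_mismatch"))
            continue
        sample = grid.sample_for(amp.exon_id, MIDPair(fm, rm))
        if sample is None:
            unassigned.append((rid, "unassigned_pair"))
            continue
        insert = core[len(amp.forward_primer): len(core) - len(amp.reverse_primer)]
        if strand == "reverse":
            insert = revcomp(insert)  # keep the insert in read orientation
        bins[(sample, amp.exon_id)].reads.append((rid, insert, strand))
    return DemuxResult(bins=bins, unassigned=unassigned, n_reads=n_reads, n_corrupt=n_corrupt)


def write_demux_report(result: DemuxResult, path: str | Path,
                       min_reads_warn: int = 100) -> None:
    """Per-bin read counts; bins under ``min_reads_warn`` are flagged (the
    assay aims to analyze every target at least 100 times per sample)."""
    with Path(path).open("w") as fh:
        fh.write("sample_id\texon\treads\tlow_coverage\n")
        for (sample, exon), b in sorted(result.bins.items()):
            flag = "yes" if b.total_reads < min_reads_warn else "no"
            fh.write(f"{sample}\t{exon}\t{b.total_reads}\t{flag}\n")
        fh.write(f"#unassigned\t{len(result.unassigned)}\n")
        fh.write(f"#corrupt_records\t{result.n_corrupt}\n")
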