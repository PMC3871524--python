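import pytest

from amplicall import refdata
from amplicall.demux import design_grid
from amplicall.refdata import AmpliconDef


@pytest.fixture(scope="session")
def amplicons():
    return refdata.load_amplicons()


@pytest.fixture(scope="session")
def by_exon(amplicons):
    return {a.exon_id: a for a in amplicons}


@pytest.fixture(scope="session")
def catalog():
    return refdata.load_catalog()


@pytest.fixture()
def single_sample_grid():
    return design_grid(1, refdata.DEFAULT_MID_INVENTORY, sample_ids=("A",))


def make_amplicon(insert: str, exon_id: int = 20, codon_start: int = 770) -> AmpliconDef:
    """Small synthetic amplicon whose whole insert is coding sequence."""
    fwd = "ACGTACGTAC"
    rev = "TTGCAGTCGA"
    if len(insert) % 3:
        raise ValueError("insert must be a whole number of codons")
    seq = fwd + insert + refdata.revcomp(rev)
    return AmpliconDef(
        exon_id=exon_id,
        forward_primer=fwd,
        reverse_primer=rev,
        reference_seq=seq,
        cds_offset=3 * codon_start - 2 - len(fwd),
        expected_length_bp=len(seq),
        codon_start=codon_start,
        codon_end=codon_start + len(insert) // 3 - 1,
    )
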