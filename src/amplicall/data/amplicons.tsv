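exon	forward_primer	reverse_primer	expected_length_bp	cds_offset	codon_start	codon_end	note
18	CATGTCTGGCACTGCTTTCC	AGGGACCTTACCTTATACACC	184	2032	688	728	synthetic reference; coordinates follow standard EGFR CDS numbering (codon N at c.3N-2..3N, signal peptide included); landmark codons match the canonical EGFR protein, filler is synthetic
19	AGCATGTGGCACCATCTCAC	ATGAGAAAAGGTGGGCCTGA	182	2144	729	761	synthetic reference; coordinates follow standard EGFR CDS numbering (codon N at c.3N-2..3N, signal peptide included); landmark codons match the canonical EGFR protein, filler is synthetic
20	AGCCACACTGACGTGCCTCT	CCTTATCTCCCCTCCCCGTA	208	2266	770	810	synthetic reference; coordinates follow standard EGFR CDS numbering (codon N at c.3N-2..3N, signal peptide included); landmark codons match the canonical EGFR protein, filler is synthetic
21	TGCAGAGCTTCTTCCCATGA	GCATGTGTTAAACAATACAGC	196	2437	825	865	synthetic reference; coordinates follow standard EGFR CDS numbering (codon N at c.3N-2..3N, signal peptide included); landmark codons match the canonical EGFR protein, filler is synthetic
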