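# Example 10-nt MID tags (exact-match barcodes); replace with the
# tag set in use on the instrument.
name	tag
MID01	ACGAGTGCGT
MID02	ACGCTCGACA
MID03	AGACGCACTC
MID04	AGCACTGTAG
MID05	ATCAGACACG
MID06	ATATCGCGAG
MID07	CGTGTCTCTA
MID08	CTCGCGTGTC
MID09	TCTCTATGCG
MID10	TGATACGTCT
MID11	CATAGTAGTG
MID12	CGAGAGATAC
MID13	GTCACGTACT
MID14	GATCGTGACA
MID15	TACGAGTATG
MID16	TAGCTGCAGT
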