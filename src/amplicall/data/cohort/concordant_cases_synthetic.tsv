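# SYNTHETIC concordant mutated cases: the validation series additionally
# contained ten cases where Sanger and deep sequencing found the same single
# mutation (nine exon 19 deletions and one L858R; nine cytology specimens
# and one biopsy, all with tumor-cell proportions above 40%). Per-case
# fractions and cell counts were not published case-by-case, so these rows
# are constructed stand-ins consistent with the published aggregates.
case_id	specimen_type	tumor_cell_percent	total_tumor_cells	diagnosis	variant	exon	mutated_read_percent	sanger_status	clinically_actionable	source
S01	C	60	15400	ACA	del E746-A750	19	35	detected	no	synthetic
S02	C	55	8200	ACA	del E746-A750	19	28	detected	no	synthetic
S03	C	70	23000	ACA	del L747-S752	19	42	detected	no	synthetic
S04	C	45	5600	NSCLC	del E746-A750	19	25	detected	no	synthetic
S05	C	65	190	ACA	del K745-A750	19	52	detected	no	synthetic
S06	C	50	12800	NSCLC	del E746-A750	19	30	detected	no	synthetic
S07	C	75	31000	ACA	del L747-S752	19	38	detected	no	synthetic
S08	C	80	154000	ACA	del E746-A750	19	45	detected	no	synthetic
S09	C	60	9100	NSCLC	L858R	21	33	detected	no	synthetic
S10	B	70	18500	ACA	del E746-A750	19	40	detected	no	synthetic
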