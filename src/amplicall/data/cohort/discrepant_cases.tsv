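# Cases where deep sequencing found mutations missed (fully or in part) by
# Sanger sequencing: one row per deep-sequencing mutation, with the
# transcribed Sanger status of that mutation. tumor_cell_percent "<40"/">40"
# records a bound where only the stratum is known.
case_id	specimen_type	tumor_cell_percent	total_tumor_cells	diagnosis	variant	exon	mutated_read_percent	sanger_status	clinically_actionable	source
67	C	5	1392	NSCLC	del E746-A751	19	2	wild_type	yes	reported
80	B	5	858	ACA bone metastasis	L858R	21	6	wild_type	yes	reported
63	C	10	3240	ACA	del K745-A750	19	2	wild_type	yes	reported
76	C	15	952	ACA	del E746-A750	19	2	wild_type	yes	reported
39	C	25	3720	NSCLC	D807G	20	16	wild_type	no	reported
57	C	35	4672	ACA LN metastasis	G721W	20	4	wild_type	no	reported
57	C	35	4672	ACA LN metastasis	R831H	21	3	wild_type	yes	reported
25	C	<40	NA	ACA	S752F	20	5.2	wild_type	no	reported
25	C	<40	NA	ACA	T785I	21	10	wild_type	no	reported
30	C	>40	NA	NSCLC	F795S	20	16	wild_type	no	reported
30	C	>40	NA	NSCLC	L858R	21	20	detected	no	reported
2	C	46	228150	ACA	del E746-A750	19	49	detected	no	reported
2	C	46	228150	ACA	P772S	20	1	wild_type	no	reported
68	B	50	1390	ACA	P691T	18	2.4	wild_type	no	reported
68	B	50	1390	ACA	T790M	20	26	detected	no	reported
68	B	50	1390	ACA	L858R	21	26	detected	no	reported
79	C	50	18000	NSCLC LN metastasis	del L747-A750 insP	19	4	wild_type	yes	reported
62	B	60	42504	ACA LN metastasis	K708N	18	2.5	wild_type	no	reported
62	B	60	42504	ACA LN metastasis	G719A	18	38	detected	no	reported
59	B	80	20784	ACA trachea metastasis	V845M	21	1.5	wild_type	no	reported
66	B	80	11410	ACA	del L747-S752	19	1.7	wild_type	yes	reported
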