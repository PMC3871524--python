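protein_change	exon	cds_change	tki_role
G719A	18	c.2156G>C	response
Exon 19 deletion	19	-	response
L858R	21	c.2573T>G	response
P772S	20	c.2314C>T	putative_response
T790M	20	c.2369C>T	resistance
R831H	21	c.2492G>A	resistance
F795S	20	c.2384T>C	undefined
T785I	20	c.2354C>T	undefined
V845M	21	c.2533G>A	undefined
P691T	18	c.2071C>A	novel
K708N	18	c.2124A>T	novel
G721W	18	c.2161G>T	novel
S752F	19	c.2255C>T	novel
D807G	20	c.2420A>G	novel
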