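id	chgvs	protein_label	patient_carriers	patient_maf_pct	control_carriers	control_maf_pct	ptc_expression_pct	rescue_note
v01	c.67-1G>A	.	3	0.16	0	0	5	.
v02	c.124_130dupGTTCGCC	p.His44fs	1	0.05	0	0	.	.
v03	c.206G>A	p.Trp69*	1	0.05	0	0	.	.
v04	c.302+1G>C	.	1	0.05	0	0	.	.
v05	c.579+1G>T	.	1	0.05	0	0	.	.
v06	c.1109dupT	p.Met370fs	1	0.06	0	0	21	Exon skipping (2%)
v07	c.1968_1977delTGCGGCCTGC	p.Cys659fs	1	0.07	0	0	.	.
v08	c.2126_2132delAGCAGGG	p.Glu709fs	6	0.36	2	0.12	41	Alternative splicing (10%)
v09	c.2134G>T	p.Glu712*	1	0.06	0	0	.	.
v10	c.2194C>T	p.Gln732*	1	0.06	0	0	.	.
v11	c.2544delC	p.Thr849fs	2	0.11	0	0	.	.
v12	c.3577+1G>C	.	1	0.05	0	0	36	.
v13	c.4008G>A	p.Trp1336*	0	0	1	0.05	27	Exon skipping (8-30%)
v14	c.4208delT	p.Leu1403fs	5	0.27	1	0.06	38	Exon skipping (3-4%)
v15	c.4382G>A	p.Trp1461*	1	0.05	0	0	.	.
v16	c.4416+2T>G	.	0	0	2	0.10	.	.
v17	c.4465C>T	p.Arg1489*	3	0.17	0	0	.	.
v18	c.5570+5G>C	.	6	0.38	7	0.38	30	.
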