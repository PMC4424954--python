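variant_id	chrom	pos	ref	alt	region	protein_change	cases	g1000_eur	nhlbi_ea	p_vs_g1000	p_vs_nhlbi	func_score	annotation
14:92979351:A:G	14	92979351	A	G	promoter		2/492 (0.41)	0/758 (0.0)		0.15			NFE2L1/MafG motif
rs368389701	14	92980256	C	A	utr5		1/492 (0.20)	0/758 (0.0)		0.39			TFBS (TAF1; POLR2A)
14:93081806:C:T	14	93081806	C	T	exon	p.A141V	1/492 (0.20)	0/758 (0.0)	0/8600 (0.0)	0.39	0.05	5	
rs3829947	14	93118038	A	G	exon	p.H215R	257/492 (52.2)	427/758 (56.3)	4902/8600 (57.0)	0.15	0.04	0	
14:93118085:C:T	14	93118085	C	T	exon	p.R231C	1/492 (0.20)	0/758 (0.0)	0/8600 (0.0)	0.39	0.05	4	
rs147329151	14	93118145	C	A	exon	p.Q251K	2/492 (0.41)	0/758 (0.0)	2/8600 (0.02)	0.15	0.02	1	
rs117068593	14	93118229	C	T	exon	p.R279C	54/492 (10.97)	129/758 (17.0)	1687/8600 (19.6)	3.1e-3	2.0e-6	4	
14:93118260:T:C	14	93118260	T	C	exon	p.L289P	1/492 (0.20)	0/758 (0.0)	0/8600 (0.0)	0.39	0.05	1	
14:93118268:T:C	14	93118268	T	C	exon	p.C292R	1/492 (0.20)	0/758 (0.0)	0/8600 (0.0)	0.39	0.05	2	
14:93118274:C:T	14	93118274	C	T	exon	p.P294S	1/492 (0.20)	0/758 (0.0)	0/8600 (0.0)	0.39	0.05	1	
14:93118310:G:A	14	93118310	G	A	exon	p.A306T	1/492 (0.20)	0/758 (0.0)	0/8600 (0.0)	0.39	0.05	0	
rs201271121	14	93118550	C	T	exon	p.P386S	1/492 (0.20)	0/758 (0.0)	0/8600 (0.0)	0.39	0.05	4	
rs3742717	14	93118668	C	T	exon	p.T425M	77/492 (15.65)	165/758 (21.8)	1458/8600 (16.9)	7.5e-3	0.45	1	
rs74074811	14	93118674	G	A	exon	p.R427Q	2/492 (0.41)	0/758 (0.0)	10/8600 (0.12)	0.15	0.11	0	
rs74074812	14	93118823	C	T	exon	p.P477S	1/492 (0.20)	0/758 (0.0)	2/8600 (0.02)	0.39	0.14	3	
rs12434929	14	93119232	G	C	exon	p.G613A	4/492 (0.81)	7/758 (0.92)	57/8600 (0.66)	0.24	0.19	1	
rs145292991	14	93125790	G	A	exon	p.D771N	1/492 (0.20)	0/758 (0.0)	2/8600 (0.02)	0.39	0.14	3	
rs147042536	14	93142861	T	C	exon	p.Y793H	5/492 (1.02)	5/758 (0.66)	54/8600 (0.63)	0.19	0.11	6	
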