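patient_id	gene	cds	protein	allele_coverage	total_coverage	af_percent	fractional_abundance_percent	copies_per_ml_plasma
4	MET	c.3328G>A	p.V1110I	16	1667	1.0	1.6	52.8
4	TP53	c.833C>G	p.P278R	27	1536	1.8	2.6	96.8
6	KRAS	c.34G>A	p.G12S	40	3201	1.2	0.9	26.4
9	KRAS	c.34G>A	p.G12S	86	3387	2.5	1.0	26.4
9	TP53	c.714_715insT	p.N239fs*1	339	5734	5.9	8.9	176
10	TP53	c.313G>T	p.G105C	32	2800	1.1	4.2	268.4
12	KRAS	c.34G>T	p.G12C	66	3084	2.1	2.2	264
13	KRAS	c.34G>A	p.G12S	7114	9999	71.1	72.8	74800
14	KRAS	c.34G>A	p.G12S	153	3003	5.1	2.9	226.6
14	TP53	c.313G>T	p.G105C	343	2750	12.5	11.4	497.2
14	SMAD4	c.1051G>A	p.D351N	612	4554	13.4	15.1	836
15	TP53	c.799C>T	p.R267W	82	3961	2.1	3.2	228.8
15	STK11	c.766G>T	p.E256*	168	6164	2.7	2.1	123.2
21	KRAS	c.35G>A	p.G12D	426	6666	6.4	10.1	682
21	KRAS	c.34G>A	p.G12S	1913	8580	22.3	24.7	1980
21	TP53	c.491A>C	p.K164T	95	5420	1.8	4.0	162.8
21	TP53	c.478A>G	p.M160V	105	5363	2.0	3.1	149.6
26	MET	c.3029C>T	p.T1010I	1994	5643	35.3	34.1	1738
26	TP53	c.578A>G	p.H193R	662	2674	24.8	26.7	1452
29	EGFR	c.2235_2249del15	p.E746_A750delELREA	140	4149	3.4	2.1	129.8
29	EGFR	c.2240T>C	p.L747S	60	4178	1.4	0.7	39.6
29	TP53	c.641A>G	p.H214R	1214	4574	26.5	34.1	2706
30	TP53	c.730G>T	p.G244C	393	5693	6.9	9.0	154
34	ERBB4	c.512G>T	p.W171L	61	2605	2.3	0	0
34	KRAS	c.34G>T	p.G12C	51	1517	3.4	5.5	52.8
34	TP53	c.716A>G	p.N239S	112	4539	2.5	3.8	35.2
35	TP53	c.711G>A	p.M237I	60	4353	1.4	0.8	46.2
36	PIK3CA	c.1624G>C	p.E542Q	2250	9973	22.6	21.6	17952
36	TP53	c.404G>A	p.C135Y	1716	2745	62.5	61.3	13684
38	KRAS	c.34G>T	p.G12C	40	3081	1.3	2.0	206.8
40	KRAS	c.34G>A	p.G12S	71	3743	1.9	3.2	149.6
40	TP53	c.830G>T	p.C277F	37	3210	1.2	0.6	39.6
40	TP53	c.742C>T	p.R248W	256	7006	3.7	4.0	257.4
40	TP53	c.734G>A	p.G245D	70	7021	1.0	1.2	81.4
40	TP53	c.578A>G	p.H193R	60	4570	1.3	0.8	52.8
51	KRAS	c.34G>T	p.G12C	46	4237	1.1	2.4	105.6
54	KRAS	c.47A>G	p.K16R	47	3208	1.5	0	0
54	KRAS	c.34G>A	p.G12S	86	3214	2.7	0	0
54	TP53	c.488A>G	p.Y163C	50	2946	1.7	1.2	259.6
57	TP53	c.715A>G	p.N239D	66	6856	1.0	1.4	33
64	TP53	c.844C>G	p.R282G	53	1814	2.9	1.3	336.6
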