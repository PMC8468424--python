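chrom	rsid	pos_b37	ref_allele	effect_allele	eaf_published	or_published	p_published
1	rs11249433	121280613	A	G	0.4	1.09	4.43e-20
2	rs13387042	217905832	A	G	0.49	0.88	8.91e-41
3	rs4973768	27416013	C	T	0.47	1.1	4.65e-22
5	rs889312	56031884	A	C	0.28	1.12	2.87e-27
6	rs2046210	151948366	G	A	0.34	1.08	2.13e-14
8	rs13281615	128355618	A	G	0.4	1.1	3.26e-22
9	rs1011970	22062134	G	T	0.17	1.06	2.68e-5
10	rs2981582	123352317	G	A	0.38	1.26	1.6e-120
10	rs10995190	64278682	G	A	0.16	0.86	1.6e-29
10	rs704010	80841148	C	T	0.38	1.08	2.94e-15
11	rs3817198	1909006	T	C	0.31	1.07	1.09e-10
11	rs614367	69328764	C	T	0.15	1.21	1.5e-45
16	rs3803662	52586341	G	A	0.26	1.24	2.71e-86
17	rs6504950	53056471	G	A	0.28	0.94	8.15e-9
21	rs2823093	16520832	G	A	0.27	0.93	2.39e-12
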