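gene	transcript	hgvs_c	hgvs_p	rsid	consequence	intron_offset	cadd	revel	mcap	clinpred	splice	mis_z	pli	domain_tags	criteria	gnomad_all.maf	gnomad_all.ac	gnomad_all.hom	gnomad_all.an	carriers	role	decoy_rule
ADAMTS15	NM_139055	c.1258G>A	p.Gly420Ser	rs767345140	missense	n.a.	33	0.506	0.011	0.641	HSF:donor_loss;NG2:donor_loss;MES:donor_loss	0.60	0.0	critical-domain	PM1+PP3	0.00006092	17	0	279072	IA83	panel	n.a.
ANGPTL6	NM_031917	c.1072G>A	p.Arg358Cys	rs147149731	missense	n.a.	13.39	0.238	n.a.	0.014	n.a.	0.64	0.0	critical-domain	PM1+BP4	0.01139	3221	32	282740	IA61	panel	n.a.
ANGPTL6	NM_031917	c.287A>G	p.Leu96Pro	rs559282550	missense	n.a.	32	0.573	n.a.	0.183	n.a.	0.64	0.0	n.a.	PP3	0.01552	447	4	28796	IA78;IA84	panel	n.a.
PCNT	NM_006031	c.959G>A	p.Arg320Lys	rs149844283	missense	n.a.	15.60	0.070	0.003	0.097	HSF:no_impact;NG2:no_impact;MES:no_impact;BDGP:no_impact	-1.33	0.0	n.a.	PM2+BP1+BP4	0.0001048	26	0	248208	IA72	panel	n.a.
PCNT	NM_006031	c.2033A>G	p.Lys678Arg	rs149623054	missense	n.a.	8.311	0.026	0.012	0.019	HSF:acceptor_gain	-1.33	0.0	n.a.	BP1+BP4	0.001591	450	2	282880	IA85	panel	n.a.
PCNT	NM_006031	c.2839G>C	p.Ala947Pro	rs1177229119	missense	n.a.	20.5	0.093	0.027	0.669	n.a.	-1.33	0.0	n.a.	PM2+PP3+BP1	0.00001595	4	0	250744	IA75	panel	n.a.
PCNT	NM_006031	c.4345C>G	p.Gln1449Glu	rs139432601	missense	n.a.	14.70	0.134	0.011	0.010	n.a.	-1.33	0.0	n.a.	BP1+BP4	0.00347	981	9	282746	IA63	panel	n.a.
PCNT	NM_006031	c.4354G>A	p.Gly1452Arg	rs143796569	missense	n.a.	22.0	0.227	n.a.	0.036	NG2:donor_gain;BDGP:donor_gain;HSF:acceptor_gain	-1.33	0.0	n.a.	PP3+BP1+BP4	0.00267	755	6	282742	IA63;IA79	panel	n.a.
PCNT	NM_006031	c.6404C>T	p.Thr2135Met	rs145710874	missense	n.a.	11.77	0.053	0.002	0.078	n.a.	-1.33	0.0	n.a.	PM2+BP1+BP4	0.00001193	3	0	251432	IA54	panel	n.a.
PCNT	NM_006031	c.6739C>T	p.His2247Tyr	rs61735812	missense	n.a.	1.606	0.038	n.a.	0.002	n.a.	-1.33	0.0	n.a.	BS4+BP1+BP4	0.01218	2866	22	235400	IA24	panel	n.a.
PCNT	NM_006031	c.7652C>T	p.Ala2551Val	rs12481791	missense	n.a.	22.5	0.109	n.a.	0.027	HSF:donor_gain;NG2:donor_gain;MES:donor_gain	-1.33	0.0	n.a.	PP3+BP1+BP4	0.01444	3848	39	266458	IA57;IA59	panel	n.a.
PCNT	NM_006031	c.7988G>A	p.Arg2663His	rs778334017	missense	n.a.	15.38	0.042	0.011	0.467	n.a.	-1.33	0.0	n.a.	PM2+BP1+BP4	0.0000115	2	0	173878	IA85	panel	n.a.
RNF213	NM_001256071	c.397C>A	p.Leu133Met	rs149177904	missense	n.a.	7.116	0.047	0.006	0.002	n.a.	2.64	0.0	n.a.	PP2+BP4	0.001089	231	1	212142	IA78	panel	n.a.
RNF213	NM_001256071	c.626T>A	p.Ile209Asn	rs144769597	missense	n.a.	0.295	0.165	0.017	0.007	n.a.	2.64	0.0	n.a.	PP2+BP4	0.001151	323	1	280624	IA78	panel	n.a.
RNF213	NM_001256071	c.8084C>T	p.Ala2695Val	rs202096577	missense	n.a.	24.4	0.325	0.018	0.187	n.a.	2.64	0.0	n.a.	PP2+BP4	0.0005313	150	0	282338	IA61	panel	n.a.
RNF213	NM_001256071	c.14030G>T	p.Trp4677Leu	rs61741961	missense	n.a.	23.4	0.602	n.a.	0.088	n.a.	2.64	0.0	n.a.	PP2+PP3	0.01047	2962	29	282802	IA79	panel	n.a.
THSD1	NM_018676	c.1666G>C	p.Gln556Glu	rs148515012	missense	n.a.	25.0	0.228	0.041	0.193	n.a.	0.49	0.0	n.a.	BP4	0.0001344	38	0	282718	IA64	panel	n.a.
THSD1	NM_018676	c.871C>T	p.Glu291Lys	rs41292808	missense	n.a.	12.32	0.090	n.a.	0.031	n.a.	0.49	0.0	n.a.	BP4	0.01864	5271	78	282824	IA17;IA49;IA54;IA90	panel	n.a.
THSD1	NM_018676	c.592G>C	p.Gln198Glu	rs186046951	missense	n.a.	18.67	0.046	0.007	0.071	n.a.	0.49	0.0	n.a.	BP4	0.0001097	31	0	282698	IA76	panel	n.a.
TMEM132B	NM_052907	c.2737C>A	p.Leu913Met	rs61940807	missense	n.a.	23.2	0.165	n.a.	0.075	n.a.	1.66	1.0	critical-domain	PM1+BP4	0.00992	2787	52	280952	IA17	panel	n.a.
PCNT	NM_006031	c.100A>G	p.Ile34Val	n.a.	missense	n.a.	5.2	0.05	0.004	0.02	n.a.	-1.33	0.0	n.a.	n.a.	0.082	23124	948	282000	IA24	decoy	maf_above_cutoff
RNF213	NM_001256071	c.2000C>T	p.Thr667Met	n.a.	missense	n.a.	9.8	0.11	0.009	0.05	n.a.	2.64	0.0	n.a.	n.a.	0.14	39480	2764	282000	IA49;IA57	decoy	maf_above_cutoff
THSD1	NM_018676	c.300G>A	p.Met100Ile	n.a.	missense	n.a.	3.1	0.03	0.002	0.01	n.a.	0.49	0.0	n.a.	n.a.	0.21	59220	6219	282000	IA61	decoy	maf_above_cutoff
ANGPTL6	NM_031917	c.50T>C	p.Val17Ala	n.a.	missense	n.a.	6.7	0.08	0.006	0.03	n.a.	0.64	0.0	n.a.	n.a.	0.0506	14269	361	282000	IA72	decoy	maf_above_cutoff
ADAMTS15	NM_139055	c.2200G>A	p.Val734Met	n.a.	missense	n.a.	11.4	0.14	0.012	0.08	n.a.	0.60	0.0	n.a.	n.a.	0.33	93060	15355	282000	IA76;IA83	decoy	maf_above_cutoff
TMEM132B	NM_052907	c.1500C>G	p.Asp500Glu	n.a.	missense	n.a.	7.9	0.09	0.007	0.04	n.a.	1.66	1.0	n.a.	n.a.	0.095	26790	1272	282000	IA85	decoy	maf_above_cutoff
TTN	NM_001267550	c.10100C>T	p.Thr3367Met	n.a.	missense	n.a.	22.1	0.31	0.02	0.21	n.a.	n.a.	n.a.	n.a.	n.a.	0.0009	254	0	282000	IA02	decoy	off_panel_gene
NOTCH3	NM_000435	c.3691C>T	p.Arg1231Cys	n.a.	missense	n.a.	25.3	0.44	0.03	0.52	n.a.	n.a.	n.a.	n.a.	n.a.	0.0001206	34	0	282000	IA05	decoy	off_panel_gene
COL3A1	NM_000090	c.2092G>A	p.Ala698Thr	n.a.	missense	n.a.	23.8	0.52	0.04	0.61	n.a.	n.a.	n.a.	n.a.	n.a.	0.0000709	20	0	282000	IA08	decoy	off_panel_gene
MYH11	NM_002474	c.3766G>A	p.Glu1256Lys	n.a.	missense	n.a.	21.6	0.28	0.015	0.33	n.a.	n.a.	n.a.	n.a.	n.a.	0.0003085	87	0	282000	IA11	decoy	off_panel_gene
SOX17	NM_022454	c.775T>A	p.Tyr259Asn	n.a.	missense	n.a.	24.9	0.61	0.05	0.71	n.a.	n.a.	n.a.	n.a.	n.a.	0.000039	11	0	282000	IA14	decoy	off_panel_gene
FBN1	NM_000138	c.4817G>A	p.Arg1606His	n.a.	missense	n.a.	26.2	0.57	0.06	0.68	n.a.	n.a.	n.a.	n.a.	n.a.	0.0000213	6	0	282000	IA20	decoy	off_panel_gene
PCNT	NM_006031	c.5000G>A	p.Arg1667His	n.a.	missense	n.a.	18.3	0.21	0.014	0.24	n.a.	-1.33	0.0	n.a.	n.a.	0.0000816	23	0	282000	n.a.	decoy	uncarried
RNF213	NM_001256071	c.9000A>G	p.Ile3000Val	n.a.	missense	n.a.	12.5	0.17	0.011	0.12	n.a.	2.64	0.0	n.a.	n.a.	0.000149	42	0	282000	n.a.	decoy	uncarried
THSD1	NM_018676	c.1200C>T	p.Pro400Leu	n.a.	missense	n.a.	19.9	0.26	0.018	0.29	n.a.	0.49	0.0	n.a.	n.a.	0.0	0	0	282000	n.a.	decoy	uncarried
LOXL2	NM_002318	c.1400G>A	p.Arg467Gln	n.a.	missense	n.a.	16.8	0.19	0.013	0.18	n.a.	n.a.	n.a.	n.a.	n.a.	0.0002092	59	0	282000	n.a.	decoy	uncarried
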