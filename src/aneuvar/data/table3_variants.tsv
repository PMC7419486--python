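gene	transcript	hgvs_c	hgvs_p	rsid	consequence	intron_offset	cadd	revel	mcap	clinpred	splice	mis_z	pli	domain_tags	criteria	gnomad_all.maf	gnomad_all.ac	gnomad_all.hom	gnomad_all.an	popgen_ikmb.maf	carriers	role	decoy_rule
NEK4	NM_003157	c.190A>T	p.Asn64Tyr	n.a.	missense	n.a.	23.7	0.452	0.113	0.984	n.a.	0.88	0.0	tyrosine-down-motif	PM1+PM2+PP3	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	candidate	n.a.
EDIL3	NM_005711	c.383G>A	p.Cys128Tyr	n.a.	missense	n.a.	29.1	0.946	0.523	0.998	n.a.	1.16	0.0	EGF-like	PM1+PM2+PP3	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	candidate	n.a.
EDNRB	NM_001201397	c.891T>G	p.Ser297Arg	n.a.	missense	n.a.	23.7	0.303	0.020	0.972	HSF:ess_gain;NG2:no_impact;MES:no_impact	1.18	0.01	n.a.	PM2	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	candidate	n.a.
DNAH9	NM_001372	c.13304T>C	p.Ile4435Thr	n.a.	missense	n.a.	24.5	0.203	0.010	0.983	n.a.	-0.04	0.0	n.a.	PM2	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	candidate	n.a.
GGA3	NM_138619	c.16G>A	p.Gly6Arg	n.a.	missense	n.a.	33.0	0.299	0.049	0.988	n.a.	-0.01	0.0	n.a.	PM2+PP3	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	candidate	n.a.
SYNDG1	NM_900001	c.101G>A	p.Arg34Gln	n.a.	missense	n.a.	27.5	0.61	0.09	0.91	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8	decoy	not_shared
SYNDG2	NM_900002	c.222C>T	p.Ser74Ser	n.a.	synonymous	n.a.	8.1	n.a.	n.a.	n.a.	HSF:donor_gain;NG2:donor_gain	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA8;IA15	decoy	not_shared
SYNDG3	NM_900003	c.333A>G	p.Asn111Asp	n.a.	missense	n.a.	25.2	0.55	0.07	0.88	n.a.	n.a.	n.a.	n.a.	n.a.	0.0000106	3	0	282000	n.a.	IA7;IA8;IA15	decoy	in_controls
SYNDG4	NM_900004	c.444T>A	p.Cys148Ser	n.a.	missense	n.a.	26.0	0.58	0.08	0.90	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	0.0002	IA7;IA8;IA15	decoy	in_controls
SYNDG5	NM_900005	c.*55G>A	n.a.	n.a.	other	n.a.	12.0	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	decoy	wrong_consequence
SYNDG6	NM_900006	c.600+5G>A	n.a.	n.a.	intronic_boundary	5	11.0	n.a.	n.a.	n.a.	HSF:donor_loss;NG2:donor_loss	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	decoy	wrong_consequence
SYNDG7	NM_900007	c.777C>G	p.His259Gln	n.a.	missense	n.a.	13.0	0.20	0.010	0.30	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	decoy	insufficient_predictor_votes
SYNDG8	NM_900008	c.888G>T	p.Trp296Cys	n.a.	missense	n.a.	23.0	0.10	0.010	0.20	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	decoy	insufficient_predictor_votes
SYNDG9	NM_900009	c.999C>T	p.Gly333Gly	n.a.	synonymous	n.a.	9.5	n.a.	n.a.	n.a.	HSF:donor_gain;NG2:no_impact;MES:no_impact	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	decoy	insufficient_splice_votes
SYNDG10	NM_900010	c.1110G>A	p.Pro370Pro	n.a.	synonymous	n.a.	7.2	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	decoy	insufficient_splice_votes
SYNDG11	NM_900011	c.1203C>A	p.Tyr401Ter	n.a.	nonsense	n.a.	10.0	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	decoy	truncating_low_cadd
SYNDG12	NM_900012	c.1300delA	p.Thr434fs	n.a.	frameshift_indel	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	IA7;IA8;IA15	decoy	truncating_low_cadd
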