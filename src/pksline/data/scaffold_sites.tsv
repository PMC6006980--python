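# diagnostic sites, 0-based offsets within each scaffold
domain	site	offset	length	kind	note
KS	triad_C	40	1	diagnostic	catalytic Cys; Gln in loading-module KSq
KS	triad_H1	75	1	diagnostic	first catalytic His
KS	triad_H2	110	1	diagnostic	second catalytic His
KS	ks_as_block	38	7	motif	active-site block TACSSGL
KS	ks_his1_block	75	5	motif	His box HGTGT
KS	ks_his2_block	105	6	motif	His box KSNIGH
AT	at_ser	47	1	diagnostic	catalytic Ser of the GHSxG motif
AT	spec_block	70	4	diagnostic	extender-unit specificity block: HAFH=malonyl, YASH=methylmalonyl
AT	at_as_block	45	5	motif	active-site GHSQG
DH	dh_his	35	1	diagnostic	catalytic His of HxxxGxxxP
DH	dh_block	35	9	motif	consensus HxxxGxxxP
ER	er_motif	40	17	motif	NADPH-binding LxHxxxGGVGxxAxxxA
KR	nadp	10	7	motif	Rossmann NADP(H)-binding GGxGxxG
KR	b_window	60	3	diagnostic	B-type signature window: LDD (or LED variant) => R-OH
KR	a_trp	72	1	diagnostic	A-type diagnostic position: Trp => S-OH
KR	triad_K	88	1	diagnostic	catalytic Lys
KR	triad_S	100	1	diagnostic	catalytic Ser
KR	triad_Y	112	1	diagnostic	catalytic Tyr
ACP	acp_ser	34	1	diagnostic	phosphopantetheinylation Ser of L/IG(x)DS
ACP	acp_block	30	5	motif	L/IG(x)DS motif block
TE	te_ser	42	1	diagnostic	catalytic Ser of GxSxG
TE	te_block	40	5	motif	active-site GxSxG
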