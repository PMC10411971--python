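human_gene	zebrafish_gene
PLTP	pltpa
ABCA1	abca1a
HMGB1	hmgb1a
HMGB1	hmgb1b
CXCR4	cxcr4a
CXCR4	cxcr4b
MFGE8	mfge8a
ITGAV	itgav
CALR	calr
LRP1	lrp1aa
LRP1	lrp1ab
SCARF1	scarf1
TGFB1	tgfb1a
TGFB1	tgfb1b
TGFBR2	tgfbr2a
IL15	il15
IL15RA	il15ra
TNF	tnfb
TNFRSF1A	tnfrsf1a
FN1	fn1a
FN1	fn1b
ITGA5	itga5
COL1A1	col1a1a
COL1A1	col1a1b
ITGA1	itga1
TIMP2	timp2a
ITGB1	itgb1a
ITGB1	itgb1b
FADD	fadd
TRADD	tradd
JAG1	jag1a
JAG1	jag1b
DLL1	dla
NOTCH2	notch2
AFDN	afdna
F11R	f11r.1
C3	c3a.1
ITGB2	itgb2
VEGFA	vegfaa
VEGFA	vegfab
KDR	kdrl
LAMB1	lamb1a
ANXA1	anxa1a
FPR2	fpr1
CXCL8	cxcl8a
CXCR1	cxcr1
CCL2	ccl2
CCR2	ccr2
CSF1	csf1a
CSF1R	csf1ra
ICAM1	icam1
ITGAL	itgal
SELP	selp
SELPLG	selplg
F13A1	f13a1a.1
ADAM10	adam10a
ADAM17	adam17a
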