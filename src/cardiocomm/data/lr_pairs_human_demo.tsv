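ligand	receptor
PLTP	ABCA1
HMGB1	CXCR4
MFGE8	ITGAV
CALR	LRP1
CALR	SCARF1
TGFB1	TGFBR2
IL15	IL15RA
IL16	CD4
TNF	TNFRSF1A
FN1	ITGA5
COL1A1	ITGA1
TIMP2	ITGB1
FADD	TRADD
JAG1	NOTCH2
DLL1	NOTCH2
AFDN	F11R
C3	ITGB2
C3	ITGAX
VEGFA	KDR
LAMB1	ITGB1
ADAM10	NOTCH2
ADAM17	ITGB1
HMGB1	AGER
ANXA1	FPR2
CXCL8	CXCR1
CCL2	CCR2
CSF1	CSF1R
ICAM1	ITGAL
SELP	SELPLG
F13A1	ITGA4
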