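# Published sponge-miRNA-mRNA ternary table: 14 lncRNA/miRNA pairs and
# 3 circRNA/miRNA pairs.  Columns: sponge, miRNA, mRNA (NA = none reported),
# mechanism.  Single-token lines mark the sponge-class sections.
lncRNA
MIAT	miR-181b	STAT3	ceRNA_sponge
SNHG1	miR-195	BCL2L2	ceRNA_sponge
Kcnq1ot1	miR-214-3p	CASPASE-1	unknown
APPAT	miR-647	NA	direct_target
MALAT1	miR-214	XBP1	direct_target
XIST	miR-130a-3p	PDE4D	direct_target
HOTAIR	miR-1	NA	unknown
UCA1	miR-1	BCL2/HSP60	unknown
RNCR3	miR-185-5p	KLF2	unknown
H19	miR-103	FADD	unknown
H19	miR-107	FADD	unknown
novlnc6	miR-133a	BMP10/NKX2-5	unknown
novlnc6	miR-2499	BMP10/NKX2-5	unknown
novlnc6	miR-30c	BMP10/NKX2-5	unknown
circRNA
circRNA_007878	let-7e	NA	ceRNA_sponge
circDLGAP4	miR-143	HECTD1	ceRNA_sponge
circR-284	miR-221	NA	ceRNA_sponge
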