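# Variant alleles detected in the 69 confirmed cases, with per-ethnicity allele
# counts.  62 distinct variants over 18 genes; allele grand total 137.
disorder	gene	cdna_hgvs	protein_hgvs	classification	Han	Miao	Dong	Tujia	Yao	total
PAHD	PAH	NM_000277.1:c.728G>A	p.(R243Q)	P	1	2	1	0	1	5
PAHD	PAH	NM_000277.1:c.1174T>A	p.(F392I)	LP	1	0	1	0	1	3
PAHD	PAH	NM_000277.1:c.158G>A	p.(R53H)	VUS	0	2	0	0	0	2
PAHD	PAH	NM_000277.1:c.1223G>A	p.(R408Q)	P	0	0	2	0	0	2
PAHD	PAH	NM_000277.1:c.1068C>A	p.(Y356*)	P	0	0	0	1	0	1
PAHD	PAH	NM_000277.1:c.462C>A	p.(Y154*)	P	0	1	0	0	0	1
PAHD	PAH	NM_000277.1:c.464G>A	p.(R155H)	P	1	0	0	0	0	1
PAHD	PAH	NM_000277.1:c.47_48del	p.(S16*)	P	1	0	0	0	0	1
PAHD	PAH	NM_000277.1:c.473G>A	p.(R158Q)	P	0	0	0	1	0	1
PAHD	PAH	NM_000277.1:c.935G>T	p.(G312V)	P	0	1	0	0	0	1
MSUD	BCKDHA	NM_000709.4:c.632C>T	p.(T211M)	LP	1	0	0	0	0	1
MSUD	BCKDHA	NM_000709.4:c.673C>T	p.(R225W)	VUS	1	0	0	0	0	1
MET	MAT1A	NM_000429.2:c.791G>A	p.(R264H)	P	1	0	0	0	0	1
BH4D	PTS	NM_000317.2:c.259C>T	p.(P87S)	P	2	0	0	0	0	2
BH4D	PTS	NM_000317.2:c.91C>A	p.(L31I)	VUS	1	0	0	0	0	1
BH4D	PTS	NM_000317.2:c.108C>A	p.(N36K)	LP	1	0	0	0	0	1
2MBG	ACADSB	NM_001609.4:c.1165A>G	p.(M389V)	P	13	12	18	4	2	49
2MBG	ACADSB	NM_001609.4:c.655G>A	p.(V219M)	P	2	0	2	0	0	4
2MBG	ACADSB	NM_001609.4:c.923G>A	p.(C308Y)	P	0	0	2	0	0	2
2MBG	ACADSB	NM_001609.4:c.746del	p.(P249Lfs*15)	LP	1	0	0	0	0	1
2MBG	ACADSB	NM_001609.4:c.1106T>A	p.(M369K)	VUS	0	0	1	0	0	1
3MCC	MCCC1	NM_020166.5:c.1331G>A	p.(R444H)	VUS	1	0	0	0	0	1
3MCC	MCCC2	NM_022132.5:c.1103del	p.(G368Vfs*70)	P	1	0	0	0	0	1
MMA	MMUT	NM_000255.4:c.1159A>C	p.(T387P)	P	1	0	0	0	0	1
MMA	MMUT	NM_000255.4:c.556A>G	p.(M186V)	LP	1	0	0	0	0	1
MMA	MMUT	NM_000255.4:c.753+3A>G	-	LP	1	0	0	0	0	1
MMA	MMUT	NM_000255.4:c.323G>A	p.(R108H)	P	1	0	0	0	0	1
HCSD	HLCS	NM_000411.8:c.1522C>T	p.(R508W)	P	1	0	0	0	0	1
HCSD	HLCS	NM_000411.8:c.1169C>G	p.(S390*)	LP	1	0	0	0	0	1
GA-I	GCDH	NM_000159.2:c.877G>A	p.(A293T)	P	1	0	0	0	0	1
GA-I	GCDH	NM_000159.2:c.881G>A	p.(R294Q)	LP	1	0	0	0	0	1
IVA	IVD	NM_014384.2:c.286G>A	p.(96S)	LP	0	1	0	0	0	1
IVA	IVD	NM_014384.2:c.758T>G	p.(V253G)	VUS	0	1	0	0	0	1
IBDD	ACAD8	NM_002225.5:c.631A>G	p.(T211A)	P	1	0	0	0	0	1
IBDD	ACAD8	NM_002225.5:c.856G>A	p.(V286M)	LP	1	0	0	0	0	1
BKD	ACAT1	NM_000019.3:c.1124A>G	p.(N375S)	P	0	1	0	0	0	1
BKD	ACAT1	NM_000019.3:c.622C>T	p.(R208X)	P	0	1	0	0	0	1
SCADD	ACADS	NM_000017.4:c.974G>A	p.(R325Q)	LP	0	1	0	0	0	1
SCADD	ACADS	NM_000017.4:c.1130C>T	p.(P377L)	P	0	1	0	0	0	1
SCADD	ACADS	NM_000017.4:c.989G>A	p.(R330H)	P	0	0	1	0	0	1
SCADD	ACADS	NM_000017.4:c.1031A>G	p.(E344G)	P	0	0	1	0	0	1
SCADD	ACADS	NM_000017.4:c.1195C>T	p.(R399W)	P	1	0	0	0	0	1
SCADD	ACADS	NM_000017.4:c.988C>T	p.(R330C)	LP	1	0	0	0	0	1
SCADD	ACADS	NM_000017.4:c.79A>C	p.(T27P)	VUS	0	0	1	0	0	1
SCADD	ACADS	NM_000017.4:c.1054G>A	p.(A352T)	P	0	0	1	0	0	1
VLCADD	ACADVL	NM_000018.4:c.1605+1G>T	-	P	0	2	0	0	0	2
VLCADD	ACADVL	NM_000018.4:c.895A>G	p.(K299E)	VUS	0	1	0	0	0	1
VLCADD	ACADVL	NM_000018.4:c.1280G>A	p.(W427*)	P	0	1	0	0	0	1
PCD	SLC22A5	NM_003060.4:c.51C>G	p.(F17L)	P	1	3	1	0	0	5
PCD	SLC22A5	NM_003060.4:c.760C>T	p.(R254*)	P	1	1	0	0	0	2
PCD	SLC22A5	NM_003060.4:c.1400C>G	p.(S467C)	P	2	0	0	0	0	2
PCD	SLC22A5	NM_003060.4:c.252C>T	p.(Y84Y)	VUS	0	1	0	0	0	1
PCD	SLC22A5	NM_003060.4:c.497G>C	p.(R166T)	VUS	0	1	0	0	0	1
PCD	SLC22A5	NM_003060.4:c.1252C>T	p.(Q418*)	P	0	0	1	0	0	1
PCD	SLC22A5	NM_003060.4:c.1195C>T	p.(R399W)	P	0	1	0	0	0	1
MCADD	ACADM	NM_000016.5:c.449_452del	p.(T150Rfs*4)	P	1	0	0	0	0	1
MCADD	ACADM	NM_000016.5:c.1085G>A	p.(G362E)	P	1	0	0	0	0	1
CD	SLC25A13	NM_014251.2:c.852_855del	p.(M285Pfs*2)	P	2	5	0	0	0	7
CD	SLC25A13	NM_014251.2:c.1751-4_1751-5ins3kb	p.(A584Vfs*2)	P	2	0	0	0	0	2
CD	SLC25A13	NM_014251.2:c.851_854del	p.(R284_M285*fs)	LP	1	0	0	0	0	1
CD	SLC25A13	NM_014251.2:c.1638_1660dup	p.(A554Gfs*17)	P	0	1	0	0	0	1
CD	SLC25A13	NM_014251.2:c.1349A>G	p.(E450G)	VUS	1	0	0	0	0	1
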