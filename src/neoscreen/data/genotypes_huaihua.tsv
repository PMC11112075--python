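# SYNTHETIC case-level genotype reconstruction for the 69 confirmed cases.
# Built to be consistent with the per-ethnicity allele counts of the variant
# table and the reported zygosity facts (21/29 2MBG homozygotes, all
# c.1165A>G; 3 c.852_855del homozygotes in CD; single detected alleles in the
# MET case and one 2MBG case).  Where the reported counts admit several
# case-level arrangements one was chosen; it is a reconstruction, not data.
# Known inconsistency: SLC22A5 (PCD) reports 13 alleles for 6 cases, one more
# than two alleles per case allow; one Miao c.51C>G allele is not representable
# here, so this file carries 12 SLC22A5 alleles.
case_id	disorder	ethnicity	allele1	allele2	zygosity
PAHD-01	PAHD	Han	PAH:c.728G>A	PAH:c.464G>A	compound-heterozygous
PAHD-02	PAHD	Han	PAH:c.1174T>A	PAH:c.47_48del	compound-heterozygous
PAHD-03	PAHD	Miao	PAH:c.728G>A	PAH:c.158G>A	compound-heterozygous
PAHD-04	PAHD	Miao	PAH:c.728G>A	PAH:c.158G>A	compound-heterozygous
PAHD-05	PAHD	Miao	PAH:c.462C>A	PAH:c.935G>T	compound-heterozygous
PAHD-06	PAHD	Dong	PAH:c.728G>A	PAH:c.1223G>A	compound-heterozygous
PAHD-07	PAHD	Dong	PAH:c.1174T>A	PAH:c.1223G>A	compound-heterozygous
PAHD-08	PAHD	Tujia	PAH:c.1068C>A	PAH:c.473G>A	compound-heterozygous
PAHD-09	PAHD	Yao	PAH:c.728G>A	PAH:c.1174T>A	compound-heterozygous
BH4D-01	BH4D	Han	PTS:c.259C>T	PTS:c.91C>A	compound-heterozygous
BH4D-02	BH4D	Han	PTS:c.259C>T	PTS:c.108C>A	compound-heterozygous
MSUD-01	MSUD	Han	BCKDHA:c.632C>T	BCKDHA:c.673C>T	compound-heterozygous
MET-01	MET	Han	MAT1A:c.791G>A	-	single-detected
2MBG-01	2MBG	Han	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-02	2MBG	Han	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-03	2MBG	Han	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-04	2MBG	Han	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-05	2MBG	Han	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-06	2MBG	Han	ACADSB:c.1165A>G	ACADSB:c.655G>A	compound-heterozygous
2MBG-07	2MBG	Han	ACADSB:c.1165A>G	ACADSB:c.655G>A	compound-heterozygous
2MBG-08	2MBG	Han	ACADSB:c.1165A>G	ACADSB:c.746del	compound-heterozygous
2MBG-09	2MBG	Miao	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-10	2MBG	Miao	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-11	2MBG	Miao	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-12	2MBG	Miao	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-13	2MBG	Miao	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-14	2MBG	Miao	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-15	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-16	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-17	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-18	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-19	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-20	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-21	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-22	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.655G>A	compound-heterozygous
2MBG-23	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.655G>A	compound-heterozygous
2MBG-24	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.923G>A	compound-heterozygous
2MBG-25	2MBG	Dong	ACADSB:c.1165A>G	ACADSB:c.1106T>A	compound-heterozygous
2MBG-26	2MBG	Dong	ACADSB:c.923G>A	-	single-detected
2MBG-27	2MBG	Tujia	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-28	2MBG	Tujia	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
2MBG-29	2MBG	Yao	ACADSB:c.1165A>G	ACADSB:c.1165A>G	homozygous
MMA-01	MMA	Han	MMUT:c.1159A>C	MMUT:c.556A>G	compound-heterozygous
MMA-02	MMA	Han	MMUT:c.753+3A>G	MMUT:c.323G>A	compound-heterozygous
3MCC-01	3MCC	Han	MCCC1:c.1331G>A	MCCC2:c.1103del	compound-heterozygous
HCSD-01	HCSD	Han	HLCS:c.1522C>T	HLCS:c.1169C>G	compound-heterozygous
IVA-01	IVA	Miao	IVD:c.286G>A	IVD:c.758T>G	compound-heterozygous
GA-I-01	GA-I	Han	GCDH:c.877G>A	GCDH:c.881G>A	compound-heterozygous
IBDD-01	IBDD	Han	ACAD8:c.631A>G	ACAD8:c.856G>A	compound-heterozygous
BKD-01	BKD	Miao	ACAT1:c.1124A>G	ACAT1:c.622C>T	compound-heterozygous
SCADD-01	SCADD	Han	ACADS:c.1195C>T	ACADS:c.988C>T	compound-heterozygous
SCADD-02	SCADD	Miao	ACADS:c.974G>A	ACADS:c.1130C>T	compound-heterozygous
SCADD-03	SCADD	Dong	ACADS:c.989G>A	ACADS:c.1031A>G	compound-heterozygous
SCADD-04	SCADD	Dong	ACADS:c.79A>C	ACADS:c.1054G>A	compound-heterozygous
VLCADD-01	VLCADD	Miao	ACADVL:c.1605+1G>T	ACADVL:c.895A>G	compound-heterozygous
VLCADD-02	VLCADD	Miao	ACADVL:c.1605+1G>T	ACADVL:c.1280G>A	compound-heterozygous
PCD-01	PCD	Han	SLC22A5:c.51C>G	SLC22A5:c.1400C>G	compound-heterozygous
PCD-02	PCD	Han	SLC22A5:c.760C>T	SLC22A5:c.1400C>G	compound-heterozygous
PCD-03	PCD	Miao	SLC22A5:c.51C>G	SLC22A5:c.760C>T	compound-heterozygous
PCD-04	PCD	Miao	SLC22A5:c.51C>G	SLC22A5:c.252C>T	compound-heterozygous
PCD-05	PCD	Miao	SLC22A5:c.497G>C	SLC22A5:c.1195C>T	compound-heterozygous
PCD-06	PCD	Dong	SLC22A5:c.51C>G	SLC22A5:c.1252C>T	compound-heterozygous
MCADD-01	MCADD	Han	ACADM:c.449_452del	ACADM:c.1085G>A	compound-heterozygous
CD-01	CD	Han	SLC25A13:c.852_855del	SLC25A13:c.852_855del	homozygous
CD-02	CD	Han	SLC25A13:c.1751-4_1751-5ins3kb	SLC25A13:c.851_854del	compound-heterozygous
CD-03	CD	Han	SLC25A13:c.1751-4_1751-5ins3kb	SLC25A13:c.1349A>G	compound-heterozygous
CD-04	CD	Miao	SLC25A13:c.852_855del	SLC25A13:c.852_855del	homozygous
CD-05	CD	Miao	SLC25A13:c.852_855del	SLC25A13:c.852_855del	homozygous
CD-06	CD	Miao	SLC25A13:c.852_855del	SLC25A13:c.1638_1660dup	compound-heterozygous
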