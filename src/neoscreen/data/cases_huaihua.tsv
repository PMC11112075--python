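# Confirmed-case counts by disorder and ethnic group, Huaihua 2015-2021
# (screened population 206,977 newborns).
disorder	class	Han	Miao	Dong	Tujia	Yao	total
PAHD	AAMD	2	3	2	1	1	9
BH4D	AAMD	2	0	0	0	0	2
MSUD	AAMD	1	0	0	0	0	1
MET	AAMD	1	0	0	0	0	1
2MBG	OAMD	8	6	12	2	1	29
MMA	OAMD	2	0	0	0	0	2
3MCC	OAMD	1	0	0	0	0	1
HCSD	OAMD	1	0	0	0	0	1
IVA	OAMD	0	1	0	0	0	1
GA-I	OAMD	1	0	0	0	0	1
IBDD	OAMD	1	0	0	0	0	1
PCD	FAOD	2	3	1	0	0	6
SCADD	FAOD	1	1	2	0	0	4
VLCADD	FAOD	0	2	0	0	0	2
BKD	FAOD	0	1	0	0	0	1
MCADD	FAOD	1	0	0	0	0	1
CD	UCD	3	3	0	0	0	6
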