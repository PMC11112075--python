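# Yearly screening volume and outcome, Huaihua 2015-2021.
year	screened	suspected_positive	confirmed
2015	14945	312	2
2016	28020	528	7
2017	35391	662	12
2018	36167	952	6
2019	34712	1043	16
2020	30378	1104	10
2021	27364	977	16
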