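component	level_label	lower_bound	relative_risk	allele_freq
snp	rs11249433		1.12	0.39
snp	rs1045485		1.14	0.87
snp	rs13387042		1.15	0.50
snp	rs4973768		1.11	0.46
snp	rs10941679		1.19	0.24
snp	rs889312		1.14	0.28
snp	rs2046210		1.27	0.35
snp	rs13281615		1.10	0.40
snp	rs1011970		1.09	0.16
snp	rs2981582		1.26	0.38
snp	rs2380205		1.11	0.56
snp	rs10995190		1.16	0.72
snp	rs704010		1.07	0.39
snp	rs3817198		1.07	0.31
snp	rs614367		1.15	0.15
snp	rs999737		1.09	0.76
snp	rs3803662		1.20	0.25
snp	rs6504950		1.05	0.73
pd	0	0.0	1.00
pd	<10	0.0	1.27
pd	10-25	10.0	2.00
pd	25-50	25.0	2.98
pd	50-75	50.0	3.70
pd	>=75	75.0	5.86
bmi	<21.79	0.0	1.00
bmi	21.79-23.30	21.79	1.16
bmi	23.30-25.02	23.30	1.13
bmi	25.02-27.64	25.02	1.28
bmi	>=27.64	27.64	1.67
clinical	menarche		1.10
clinical	first_birth		1.24
clinical	bbd		1.65
clinical	fh		2.07
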