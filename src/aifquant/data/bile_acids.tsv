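# Bile-acid panel: 26 quantified analytes plus deuterated internal standards.
# expected_rt in minutes on the 19-min water/methanol gradient; nominal IS
# concentration in µM (mixture nominal).
name	class_tag	formula	adduct	expected_rt	rt_source	internal_standard_ref	is_internal_standard	nominal_is_concentration
CA	bile-acid	C24H40O5	[M-H]-	7.4	standard	CA-d5	0
CDCA	bile-acid	C24H40O4	[M-H]-	9.0	standard	CDCA-d4	0
DCA	bile-acid	C24H40O4	[M-H]-	9.3	standard	DCA-d5	0
LCA	bile-acid	C24H40O3	[M-H]-	11.2	standard	LCA-d4	0
UDCA	bile-acid	C24H40O4	[M-H]-	6.9	standard	UDCA-d4	0
HCA	bile-acid	C24H40O5	[M-H]-	7.1	standard	CA-d5	0
HDCA	bile-acid	C24H40O4	[M-H]-	7.7	standard	HDCA-d5	0
MDCA	bile-acid	C24H40O4	[M-H]-	8.4	standard	HDCA-d5	0
aMCA	bile-acid	C24H40O5	[M-H]-	4.9	standard	CA-d5	0
bMCA	bile-acid	C24H40O5	[M-H]-	5.4	standard	CA-d5	0
wMCA	bile-acid	C24H40O5	[M-H]-	4.6	standard	CA-d5	0
GCA	glycine-conjugate	C26H43NO6	[M-H]-	5.0	standard	GCA-d5	0
GCDCA	glycine-conjugate	C26H43NO5	[M-H]-	6.2	standard	GCDCA-d7	0
GDCA	glycine-conjugate	C26H43NO5	[M-H]-	6.5	standard	GDCA-d4	0
GLCA	glycine-conjugate	C26H43NO4	[M-H]-	8.1	standard	GCDCA-d7	0
GUDCA	glycine-conjugate	C26H43NO5	[M-H]-	4.4	standard	GUDCA-d5	0
GHDCA	glycine-conjugate	C26H43NO5	[M-H]-	4.7	standard	GUDCA-d5	0
TCA	taurine-conjugate	C26H45NO7S	[M-H]-	4.1	standard	TCA-d5	0
TCDCA	taurine-conjugate	C26H45NO6S	[M-H]-	5.2	standard	TCDCA-d5	0
TDCA	taurine-conjugate	C26H45NO6S	[M-H]-	5.6	standard	TDCA-d5	0
TLCA	taurine-conjugate	C26H45NO5S	[M-H]-	6.8	standard	TLCA-d5	0
TUDCA	taurine-conjugate	C26H45NO6S	[M-H]-	3.6	standard	TUDCA-d5	0
THDCA	taurine-conjugate	C26H45NO6S	[M-H]-	3.9	standard	TUDCA-d5	0
7S-CA	sulfate	C24H40O8S	[M-H]-	3.3	standard	CA-d5	0
3S-TCA	taurine-conjugate+sulfate	C26H45NO10S2	[M-H]-	2.9	standard	TCA-d5	0
3S-TLCA	taurine-conjugate+sulfate	C26H45NO8S2	[M-H]-	4.8	standard	TLCA-d5	0
CA-d5	bile-acid	C24H35D5O5	[M-H]-	7.4	standard		1	25
CDCA-d4	bile-acid	C24H36D4O4	[M-H]-	9.0	standard		1	25
DCA-d5	bile-acid	C24H35D5O4	[M-H]-	9.3	standard		1	25
LCA-d4	bile-acid	C24H36D4O3	[M-H]-	11.2	standard		1	25
UDCA-d4	bile-acid	C24H36D4O4	[M-H]-	6.9	standard		1	25
HDCA-d5	bile-acid	C24H35D5O4	[M-H]-	7.7	standard		1	25
GCA-d5	glycine-conjugate	C26H38D5NO6	[M-H]-	5.0	standard		1	25
GCDCA-d7	glycine-conjugate	C26H36D7NO5	[M-H]-	6.2	standard		1	25
GDCA-d4	glycine-conjugate	C26H39D4NO5	[M-H]-	6.5	standard		1	25
GUDCA-d5	glycine-conjugate	C26H38D5NO5	[M-H]-	4.4	standard		1	25
TCA-d5	taurine-conjugate	C26H40D5NO7S	[M-H]-	4.1	standard		1	25
TCDCA-d5	taurine-conjugate	C26H40D5NO6S	[M-H]-	5.2	standard		1	25
TDCA-d5	taurine-conjugate	C26H40D5NO6S	[M-H]-	5.6	standard		1	25
TLCA-d5	taurine-conjugate	C26H40D5NO5S	[M-H]-	6.8	standard		1	25
TUDCA-d5	taurine-conjugate	C26H40D5NO6S	[M-H]-	3.6	standard		1	25
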