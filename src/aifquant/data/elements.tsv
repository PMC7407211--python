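symbol	monoisotopic_mass	comment
C	12.000000000	12C defines the unified atomic mass scale
H	1.007825032	1H
D	2.014101778	2H, pseudo-element for deuterated internal standards
N	14.003074005	14N
O	15.994914620	16O
P	30.973761998	31P
S	31.972071174	32S
Na	22.989769282	23Na
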