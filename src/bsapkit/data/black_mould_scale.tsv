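# Black & Mould residue hydrophobicity scale (Black SD, Mould DR,
# Anal Biochem 193:72-82, 1991), normalized to [0, 1].
# Loaders shift the scale so that GLY = 0; on the shifted scale negative
# values are hydrophilic (ARG, at -0.50, is the most hydrophilic residue).
residue_name	hydrophobicity
ALA	0.616
ARG	0.000
ASN	0.236
ASP	0.028
CYS	0.680
GLN	0.251
GLU	0.043
GLY	0.501
HIS	0.165
ILE	0.943
LEU	0.943
LYS	0.283
MET	0.738
PHE	1.000
PRO	0.711
SER	0.359
THR	0.450
TRP	0.878
TYR	0.880
VAL	0.825
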