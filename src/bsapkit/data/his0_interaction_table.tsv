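# Interaction inputs for scoring the affinity of a protein surface for
# neutral free histidine (HIS0), per interaction type and residue type.
# energy_kcal_per_mol: pairwise HIS0-residue interaction energies for
#   cation-pi, pi-pi stacking and hydrogen-pi interactions (quantum-chemistry
#   derived literature values); empty for h_bond rows.
# hydrophobicity: shifted Black & Mould value used by the hydrogen-bond
#   score; empty for energy-based rows.
# saa_fc_avg_nm2 / saa_fab_avg_nm2: trajectory-averaged accessible area of
#   each residue type on the Fc and Fab fragments of the COE3 antibody
#   (3 significant figures).
# saa_exposed_nm2: fully-exposed side-chain area of the residue type from an
#   extended Ala-X-Ala trimer in water.
interaction_type	residue_name	energy_kcal_per_mol	hydrophobicity	saa_fc_avg_nm2	saa_fab_avg_nm2	saa_exposed_nm2
cation_pi	ARG	-8.193		12.9	12.5	2.22
cation_pi	LYS	-9.268		34.5	28.3	1.93
pi_pi	PHE	-0.093		4.7	2.5	1.9
pi_pi	TYR	-0.098		9.4	9.5	2.0
pi_pi	TRP	-0.535		0.7	0.3	2.3
pi_pi	ARG	-2.402		12.9	12.3	2.2
h_pi	PHE	-2.735		4.7	2.5	1.9
h_pi	TYR	-2.599		9.4	9.5	2.0
h_pi	TRP	-3.679		0.7	0.3	2.3
h_bond	ARG		-0.50	12.9	12.5	2.2
h_bond	ASN		-0.27	17.7	8.4	1.4
h_bond	ASP		-0.47	9.9	8.2	1.2
h_bond	GLN		-0.25	17.6	11.2	1.6
h_bond	GLU		-0.46	20.2	9.7	1.5
h_bond	LYS		-0.22	34.5	28.3	1.9
h_bond	SER		-0.14	13.9	34.9	1.0
h_bond	THR		-0.05	9.7	19.3	1.2
h_bond	HIS		-0.34	9.7	2.1	1.6
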