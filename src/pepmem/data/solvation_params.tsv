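# Solvation reference free energies for the Gaussian solvent-exclusion model,
# EEF1-style group parameterization at residue/atom-group granularity.
# dg_water: hydration free energy of the fully exposed group (kcal/mol),
# anchored on experimental side-chain-analog hydration data; dg_chex:
# dg_water plus the experimental water->cyclohexane transfer free energy of
# the analog (amide transfer split between backbone N-H and C=O).
# volume: group volume, A^3. lambda: correlation length of the exclusion
# shell, A. vdw_radius: van der Waals radius of the group, A.
# Ionizable side chains (LYS, ARG, ASP, GLU) carry the larger transfer
# penalty of the charged species and the longer lambda of ionic groups.
solv_key	dg_water	dg_chex	volume	lambda	vdw_radius
BB_N	-5.95	-2.95	11.2	3.5	1.75
BB_CA	-0.25	-0.90	23.7	3.5	2.00
BB_C	0.00	0.00	14.7	3.5	2.00
BB_O	-5.33	-2.23	10.8	3.5	1.60
HYD	0.00	0.00	0.0	3.5	0.80
SC_ALA	1.94	0.13	30.0	3.5	2.10
SC_GLY	0.00	0.00	0.0	3.5	1.00
SC_SER	-5.06	-1.66	25.0	3.5	1.90
SC_THR	-4.88	-2.31	42.0	3.5	2.10
SC_CYS	-1.24	-2.52	35.0	3.5	2.00
SC_VAL	1.99	-2.05	64.0	3.5	2.30
SC_LEU	2.28	-2.64	78.0	3.5	2.40
SC_ILE	2.15	-2.77	78.0	3.5	2.40
SC_MET	-1.48	-3.83	80.0	3.5	2.40
SC_PRO	1.00	-2.00	52.0	3.5	2.20
SC_PHE	-0.76	-3.74	90.0	3.5	2.50
SC_TRP	-5.88	-8.21	125.0	3.5	2.60
SC_TYR	-6.11	-5.97	95.0	3.5	2.50
SC_ASN	-9.68	-3.04	50.0	3.5	2.10
SC_GLN	-9.38	-3.84	66.0	3.5	2.20
SC_HIS	-10.27	-5.61	70.0	3.5	2.30
SC_ASP	-11.00	1.00	42.0	6.0	2.10
SC_GLU	-11.00	1.00	58.0	6.0	2.20
SC_LYS	-9.50	0.50	72.0	6.0	2.30
SC_ARG	-11.50	0.00	90.0	6.0	2.40
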