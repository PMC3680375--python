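# Compilation of experimental membrane binding free energies of helical
# antimicrobial peptides (molarity standard state, kcal/mol) together with
# implicit-membrane transfer energies: dW = <dW> (average transfer energy,
# membrane-bound ensemble) and davgW = change in average effective energy
# between independent membrane and water ensembles. Uncertainties are SEM
# over four independent runs. The SOPC/POPG entry for LL-37 was interpolated
# from measurements at other anionic fractions.
peptide	pdb_id	lipids	dG_c0	dW	dW_sem	davgW	davgW_sem
Alamethicin	1amt	DOPC	-5.77	-8.6	0.2	-8.2	0.4
Mastoparan X	2czp	POPC	-4.7	-4.2	0.8	-4.0	0.6
delta-hemolysin	2kam	POPC	-6.0	-12.6	0.5	-17.6	7.7
CM-15	2jmy	DMPC	-4.72	-8.3	0.9	-5.1	1.8
CM-15	2jmy	DMPG	-5.49	-15.5	0.3	-14.1	3.2
Dermadistinctin K	2k9b	eggPC	-3.97	-3.1	1.7	-2.5	3.1
LL-37	2k6o	SOPC	-6.16	-12.7	0.4	-1.8	3.8
LL-37	2k6o	SOPC/POPG(7:3)	-8.79	-19.1	1.9	-6.9	3.6
Magainin	2mag	POPC	-3.7	-5.4	0.6	-1.8	3.1
Magainin	2mag	POPC/POPG(3:1)	-5.98	-10.7	1.0	-7.6	2.8
Melittin	2mlt	DOPC	-5.1	-13.1	0.7	-5.4	1.2
Melittin	2mlt	POPC/POPG(8:2)	-8.2	-18.6	2.5	-17.0	4.1
Pardaxin	1xc0	POPC	-6.21	-22.1	0.8	-7.0	2.3
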