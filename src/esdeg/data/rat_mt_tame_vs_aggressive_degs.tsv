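gene_id	gene_name	log2_fold	p_adj
Defb17	defensin beta 17	7.31	1.86e-3
Lilrb3l	leukocyte immunoglobulin-like receptor, subfamily B member 3-like	5.71	9.15e-2
Loxhd1	lipoxygenase homology PLAT domains 1	4.02	7.91e-2
Si	sucrase-isomaltase	3.30	8.66e-2
Ascl3	achaete-scute family bHLH transcription factor 3	2.82	3.16e-4
Pcdhga1	protocadherin gamma subfamily A, 1	2.80	2.21e-2
LOC100910802		2.25	6.64e-2
Fcgr2b	Fc gamma receptor IIb	2.01	2.46e-2
Crispld1	cysteine-rich secretory protein LCCL domain containing 1	1.49	7.40e-2
Cthrc1	collagen triple helix repeat containing 1	1.44	6.13e-2
Slc7a11	solute carrier family 7 member 11	1.37	9.84e-2
Nmnat1	nicotinamide nucleotide adenylyltransferase 1	1.31	1.76e-11
Htr3a	5-hydroxytryptamine receptor 3A	1.30	4.33e-2
Mpeg1	macrophage expressed 1	1.28	8.30e-4
Slfn13	schlafen family member 13	1.26	6.30e-2
Sync	syncoilin, intermediate filament protein	1.19	5.31e-2
Olfml1	olfactomedin-like 1	1.14	6.73e-2
Pter	phosphotriesterase related	1.13	7.16e-2
Col15a1	collagen type XV alpha 1 chain	1.12	5.45e-2
Morn1	MORN repeat containing 1	1.10	1.43e-4
Sstr2	somatostatin receptor 2	-1.01	2.46e-2
Retsat	retinol saturase	-1.03	1.33e-2
Gpd1	glycerol-3-phosphate dehydrogenase 1	-1.05	2.46e-2
Aqp9	aquaporin 9	-1.22	9.89e-2
Spint1	serine peptidase inhibitor, Kunitz type 1	-1.29	1.43e-4
Arc	activity-regulated cytoskeleton-associated protein	-1.35	6.13e-2
Tcte1	t-complex-associated testis expressed 1	-1.41	6.30e-2
Ttc22	tetratricopeptide repeat domain 22	-1.44	5.08e-2
Krt2	keratin 2	-1.54	8.63e-5
Fos	Fos proto-oncogene, AP-1 transcription factor subunit	-1.63	6.87e-2
Sypl2	synaptophysin-like 2	-1.65	8.72e-2
Lypd3	Ly6/Plaur domain containing 3	-1.86	5.08e-2
Htr5b	5-hydroxytryptamine (serotonin) receptor 5B	-1.94	9.17e-2
Fosb	FosB proto-oncogene, AP-1 transcription factor subunit	-1.95	2.46e-2
Hspa1a	heat shock protein family A (Hsp70) member 1A	-2.10	4.25e-2
Hspa1b	heat shock protein family A (Hsp70) member 1B	-2.19	3.42e-8
Vip	vasoactive intestinal peptide	-2.35	8.93e-3
RGD1565611		-2.94	6.69e-2
Tac3	tachykinin precursor 3	-3.64	2.46e-2
Ptpn20	protein tyrosine phosphatase, non-receptor type 20	-4.49	9.17e-2
Hcrt	hypocretin neuropeptide precursor	-5.15	6.56e-2
Hbb-b1	hemoglobin, beta adult major chain	-7.78	1.09e-5
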