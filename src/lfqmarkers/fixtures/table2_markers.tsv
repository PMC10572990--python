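subnetwork	protein_name	gene_name	vs_ct	vs_nic	vs_pcp
Oxidative stress	Peptidyl-prolyl cis-trans isomerase FKBP1A	Fkbp1a	Up	Up	Up
Oxidative stress	Heat shock 70 kDa protein 1B	Hspa1b	Down	Down	Down
Oxidative stress	Heat shock-related 70 kDa protein 2	Hspa2	Up	Up	Up
Oxidative stress	Ras-related protein Rab-4A	Rab4a	Up	Up	Up
Oxidative stress	Peroxiredoxin-1	Prdx1	Up	Up	Up
Oxidative stress	V-type proton ATPase catalytic subunit A	Atp6v1a	Up	Up	Up
Oxidative stress	Parkinson disease protein 7 homolog	Park7	Up	Up	Up
Oxidative stress	Glutathione S-transferase P 1	Gstp1	Up	Up	Up
Oxidative stress	Glutathione S-transferase Mu 1	Gstm1	Up	Up	Up
Oxidative stress	Protein disulfide-isomerase A3	Pdia3	Up	Up	Up
Energy metabolism	Gamma-enolase	Eno2	Up	Up	Up
Energy metabolism	Glyceraldehyde-3-phosphate dehydrogenase_testis-specific	Gapdhs	Down	Down	Down
Energy metabolism	Glucose-6-phosphate isomerase	Gpi	Up	Up	Up
Energy metabolism	Pyruvate kinase PKLR	Pklr	Up	Up	Up
Energy metabolism	Aspartate aminotransferase_mitochondrial	Got2	Up	Up	Up
Energy metabolism	Citrate synthase_mitochondrial	Cs	Down	Down	Down
Energy metabolism	Acetyl-CoA acetyltransferase_mitochondrial	Acat1	Down	Down	Down
Energy metabolism	Glutamine synthetase	Glul	Up	Up	Up
Serine/threonine-protein phosphatases	Serine/threonine-protein phosphatase PP1-gamma catalytic subunit	Ppp1cc	Up	Up	Up
Serine/threonine-protein phosphatases	Serine/threonine-protein phosphatase 2A catalytic subunit beta isoform	Ppp2cb	Up	Up	Up
Serine/threonine-protein phosphatases	Serine/threonine-protein phosphatase 2A 65 kDa regulatory subunit A alpha isoform	Ppp2r1a	Up	Up	Up
Serine/threonine-protein phosphatases	Isoform 2 of Liprin-alpha-3	Ppfia3	Up	Up	Up
Neurite outgrowth	Thy-1 membrane glycoprotein	Thy1	Down	Down	Down
Neurite outgrowth	Transgelin-3	Tagln3	Up	Up	Up
Neurite outgrowth	Drebrin	Dbn1	Up	Up	Up
Neurite outgrowth	Neuromodulin	Gap43	Down	Down	Down
Neurite outgrowth	Myristoylated alanine-rich C-kinase substrate	Marcks	Down	Down	Down
Neurite outgrowth	Actin_alpha skeletal muscle	Acta1	Up	Up	Up
G protein-coupled receptors signaling	Guanine nucleotide-binding protein subunit alpha-12	Gna12	Up	Up	Up
G protein-coupled receptors signaling	Guanine nucleotide-binding protein G(I)/G(S)/G(T) subunit beta-2	Gnb2	Up	Up	Up
G protein-coupled receptors signaling	Guanine nucleotide-binding protein G(olf) subunit alpha	Gnal	Up	Up	Up
Septin cytoskeleton	Septin-8	Septin8	Up	Up	Up
Septin cytoskeleton	Septin-10	Septin10	Down	Down	Down
Cell cycle	Ras-related protein Rab-37	Rab37	Up	Up	Up
Cell cycle	HMG box transcription factor BBX	Bbx	Up	Up	Up
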