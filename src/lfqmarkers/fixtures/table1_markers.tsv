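subnetwork	protein_name	gene_name	vs_ct	vs_nic	vs_pcp
Synaptic transmission	Amphiphysin	Amph	Down	Down	Down
Synaptic transmission	Synaptophysin	Syp	Down	Down	Down
Synaptic transmission	Microtubule-associated protein 2	Map2	Down	Down	Down
Synaptic transmission	Mitogen-activated protein kinase 3	Mapk3	Down	Down	Down
Actin cytoskeleton	Actin-related protein 3B	Actr3b	Down	Down	Down
Actin cytoskeleton	Adenylyl cyclase-associated protein 1	Cap1	Down	Down	Down
Serine/threonine-protein phosphatases	Serine/threonine-protein phosphatase 2B catalytic subunit alpha isoform	Ppp3ca	Down	Down	Down
Serine/threonine-protein phosphatases	Serine/threonine-protein phosphatase PP1-beta catalytic subunit	Ppp1cb	Down	Down	Down
Nervous system development	Dihydropyrimidinase-related protein 5	Dpysl5	Down	Down	Down
Nervous system development	Dihydropyrimidinase-related protein 1	Crmp1	Down	Down	Down
Energy metabolism	Malate dehydrogenase_cytoplasmic	Mdh1	Down	Down	Down
Energy metabolism	Phosphoglycerate kinase 2	Pgk2	Down	Down	Down
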