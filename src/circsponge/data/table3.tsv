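circRNA	fold_change	regulation	miRNA	target_gene	pathway	functions
circRNA.7079	62.85875487	Up	mmu-miR-761	Lgals3	Wnt/β-catenin signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-1907	Lgals3	Wnt/β-catenin signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-326-5p	BIRC5	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-3474	Pbk	Pbk/Akt signaling pathway	Proliferation/Migration/Angiogenesis
circRNA.7078	31.09694285	Up	mmu-miR-761	Top2a	Her2 signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-1907	Ms4a6c	TCR signaling pathway	Proliferation
			mmu-miR-3474	Cd44	Wnt/β-catenin signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-5710	Knstrn	TCR signaling pathway	Proliferation
circRNA.27570	17.1963371	Up	mmu-miR-9768-3p	Cd44	Wnt/β-catenin signaling pathway	Proliferation/Migration/Angiogenesis
circRNA.26810	13.10873913	Up	mmu-miR-709	BIRC5	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-1956	Lgals3	Wnt/β-catenin signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-1935	Vim	STAT3 signaling pathway	Proliferation/Migration/Angiogenesis
circRNA.5566	12.04671542	Up	mmu-miR-721	Pten	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-1953	Pten	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
circRNA.27348	11.91692033	Up	mmu-miR-695	Thbs1	STAT3 signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-763	Pten	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
circRNA.6727	11.8892439	Up	mmu-miR-871-3p	Tnfrsf10b	Akt Signaling Pathway.	Proliferation/Migration/Angiogenesis
			mmu-miR-1190	Pten	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
circRNA.26807	11.54191573	Up	mmu-miR-709	BIRC5	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-1935	Pten	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
circRNA.15929	11.52291449	Up	mmu-miR-450b-3p	Fcer1g	leukocyte migration; cytokine production	Proliferation/Migration/Angiogenesis
			mmu-miR-1843b-5p	Fn1	TGF-β signaling pathway	Proliferation/Migration/Angiogenesis
circRNA.27347	11.31077366	Up	mmu-miR-125a-5p	Irf5	Wnt signaling pathway	Proliferation/Angiogenesis
			mmu-miR-343	Thbs1	Wnt/β-catenin signaling pathway	Proliferation/Migration/Angiogenesis
			mmu-miR-691	Pten	PI3K-Akt signaling pathway	Proliferation/Migration/Angiogenesis
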