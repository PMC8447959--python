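circRNA	fold_change	regulation	chromosome	strand	host_gene	p_value
circRNA.7079	62.85875487	Up	chr14	+	Lgals3	0.004436
circRNA.7078	31.09694285	up	chr14	+	Lgals3	0.011314
circRNA.6777	21.70369315	up	chr14	+	Pbk	0.032084
circRNA.17120	19.44192413	up	chr1	+	Cd84	0.030409
circRNA.10854	18.12036937	up	chr11	−	Top2a	0.020119
mmu-circRNA483	17.26274244	up	chr19	+	Ms4a6c	0.016317
circRNA.27570	17.1963371	up	chr2	−	Cd44	0.008235
circRNA.27321	16.0267925	up	chr2	+	Knstrn	0.042293
circRNA.538	14.81831851	up	chr19	+	Ms4a6c	0.003396
circRNA.8591	13.55325989	up	chr13	−	n/a	0.000530
circRNA.6335	4.509393859	down	chr15	+	C1qtnf3	0.0019097
mmu_circ_0010846	3.761647531	down	chr3	−	Bcan	0.0048737
circRNA.16626	3.673922594	down	chr1	−	Col19a1	0.0016594
circRNA.12533	3.436555425	down	chr11	−	Tenm2	0.0367338
circRNA.6638	3.15487569	down	chr14	+	n/a	0.0340403
circRNA.27485	3.15149557	down	chr2	−	Ano3	0.0114666
circRNA.21851	3.027841911	down	chr5	+	Ksr2	0.0297605
circRNA.4430	3.010502122	down	chr16	−	Prodh	0.0002868
mmu_circ_0012585	2.961510524	down	chr5	+	Rgs12	0.0131907
circRNA.16625	2.958448619	down	chr1	−	Col19a1	0.0384322
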