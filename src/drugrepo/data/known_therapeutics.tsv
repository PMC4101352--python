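phenotype	gene	drug_name	status	action	source
T1D	PPARG	Rosiglitazone	Approved	agonist	ttd
T1D	DGKA	Vitamin E	Approved	unknown	drugbank
T2D	CTSD	Insulin Regular	Approved	unknown	drugbank
T2D	PPARA	Aleglitazar	Phase III	agonist	ttd
T2D	NR3C1	ISIS-GCCR	Preclinical	antisense	ttd
T2D	TCF7L2	Repaglinide	Unknown	unknown	pharmgkb
T2D	PPARD	Bezafibrate	Approved	agonist	drugbank
T2D	RB1	Insulin, porcine	Approved	unknown	drugbank
T2D	HSD11B1	INCB13739	Phase IIa	inhibitor	ttd
RA	TNF	Infliximab	Approved	inhibitor	drugbank
RA	ITGA4	CDP323	Phase II	antagonist	ttd
RA	JAK2	INCB18424	Phase III	inhibitor	ttd
RA	IL15	AMG-714	Discontinued in phase I	inhibitor	ttd
RA	CCL2	MCP-1	Preclinical	inhibitor	ttd
RA	PRKCA	Vitamin E	Approved	unknown	drugbank
HT	DRD1	Fenoldopam	Approved	agonist	ttd
HT	AGTR1	Valsartan	Approved	antagonist	ttd
HT	CNR1	AZD1175	Discontinued in phase I	antagonist	ttd
HT	AGT	Benazepril	Unknown	unknown	pharmgkb
HT	GUCY1A2	Isosorbide Mononitrate	Approved	inducer	drugbank
BD	SLC6A2	Imipramine	Approved	inhibitor	drugbank
BD	AGTR1	Valsartan	Approved	antagonist	drugbank
CAD	MYC	AVI4126	Phase I/II	antisense	ttd
CAD	PLG	Urokinase	Approved	activator	drugbank
CAD	NOS3	ACCLAIM	Phase III	stimulator	ttd
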