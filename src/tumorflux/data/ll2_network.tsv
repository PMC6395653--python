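# LL/2 Lewis lung carcinoma central-carbon-metabolism network, two compartments
# (blood microenvironment + single intracellular compartment).
# Reconstruction v1: 52 metabolites, 35 reactions. Glucose transport is lumped
# into VHK and lactate export into VLDH; nucleotide synthesis is lumped into
# Vgrowth. ACCOA (mitochondrial) and ACCOAC (cytosolic, lipogenic) are distinct
# pools so that ATP citrate lyase is the sole route into lipogenesis.
#
# Record types:
#   metabolite <tab> id <tab> name <tab> compartment(blood|cell)
#   reaction   <tab> id <tab> equation <tab> reversible(0|1) <tab> enzyme <tab> drug_effects <tab> notes
# Equations: "1 A + 2 B -> 1 C"; "<->" marks reversible; an empty product side is a sink.
# drug_effects: semicolon-separated drug:mode pairs (mode inhibit|activate).
#
# --- blood (tumor microenvironment) metabolites ---
metabolite	EGLC	extracellular glucose	blood
metabolite	EGLN	extracellular glutamine	blood
metabolite	EGLU	extracellular glutamate	blood
metabolite	LAC	extracellular lactate	blood
metabolite	ALA	extracellular alanine	blood
metabolite	ARG	extracellular arginine	blood
metabolite	ASN	extracellular asparagine	blood
metabolite	ASP	extracellular aspartate	blood
metabolite	GLY	extracellular glycine	blood
metabolite	HIS	extracellular histidine	blood
metabolite	ILE	extracellular isoleucine	blood
metabolite	LEU	extracellular leucine	blood
metabolite	LYS	extracellular lysine	blood
metabolite	SER	extracellular serine	blood
metabolite	THR	extracellular threonine	blood
metabolite	TYR	extracellular tyrosine	blood
metabolite	VAL	extracellular valine	blood
metabolite	NH4	extracellular ammonia	blood
metabolite	CO2	carbon dioxide	blood
metabolite	H2O	water	blood
metabolite	O2	oxygen	blood
metabolite	DICLO	extracellular diclofenac	blood
metabolite	HCIT	extracellular hydroxycitrate	blood
metabolite	LA	extracellular lipoic acid	blood
metabolite	METF	extracellular metformin	blood
metabolite	Pi	inorganic phosphate	blood
# --- intracellular metabolites ---
metabolite	G6P	glucose-6-phosphate	cell
metabolite	F6P	fructose-6-phosphate	cell
metabolite	GAP	glyceraldehyde-3-phosphate	cell
metabolite	PEP	phosphoenolpyruvate	cell
metabolite	PYR	pyruvate	cell
metabolite	R5P	ribulose-5-phosphate	cell
metabolite	ACCOA	acetyl-CoA (mitochondrial)	cell
metabolite	ACCOAC	acetyl-CoA (cytosolic, lipogenic)	cell
metabolite	CIT	citrate	cell
metabolite	AKG	alpha-ketoglutarate	cell
metabolite	SUCCOA	succinyl-CoA	cell
metabolite	SUC	succinate	cell
metabolite	FUM	fumarate	cell
metabolite	MAL	malate	cell
metabolite	OXA	oxaloacetate	cell
metabolite	PALM	palmitate	cell
metabolite	GLU	glutamate	cell
metabolite	ATP	adenosine triphosphate	cell
metabolite	ADP	adenosine diphosphate	cell
metabolite	AMP	adenosine monophosphate	cell
metabolite	NAD	NAD+ (oxidized)	cell
metabolite	NADH	NADH (reduced)	cell
metabolite	NADP	NADP+ (oxidized)	cell
metabolite	NADPH	NADPH (reduced)	cell
metabolite	FAD	FAD (oxidized)	cell
metabolite	FADH2	FADH2 (reduced)	cell
# --- glycolysis (glucose transport lumped into VHK, lactate export into VLDH) ---
reaction	VHK	1 EGLC + 1 ATP -> 1 G6P + 1 ADP	0	hexokinase (incl. glucose transport)	DICLO:inhibit	diclofenac target
reaction	VPGI	1 G6P -> 1 F6P	0	phosphoglucose isomerase
reaction	VPFK	1 F6P + 1 ATP -> 2 GAP + 1 ADP	0	phosphofructokinase + aldolase + TPI
reaction	VGAPDH	1 GAP + 1 Pi + 1 ADP + 1 NAD -> 1 PEP + 1 ATP + 1 NADH + 1 H2O	0	GAPDH + PGK + PGM + enolase
reaction	VPK	1 PEP + 1 ADP -> 1 PYR + 1 ATP	0	pyruvate kinase
reaction	VLDH	1 PYR + 1 NADH <-> 1 LAC + 1 NAD	1	lactate dehydrogenase (incl. MCT export)	DICLO:inhibit	negative flux = lactate uptake
# --- pentose phosphate pathway (oxidative branch, lumped) ---
reaction	VG6PDH	1 G6P + 2 NADP -> 1 R5P + 1 CO2 + 2 NADPH	0	glucose-6-phosphate dehydrogenase (ox. PPP)
# --- pyruvate branch point ---
reaction	VPDH	1 PYR + 1 NAD -> 1 ACCOA + 1 CO2 + 1 NADH	0	pyruvate dehydrogenase	LA:activate	alpha-lipoic-acid target
reaction	VPC	1 PYR + 1 ATP + 1 CO2 -> 1 OXA + 1 ADP + 1 Pi	0	pyruvate carboxylase
# --- TCA cycle ---
reaction	VCS	1 ACCOA + 1 OXA + 1 H2O -> 1 CIT	0	citrate synthase
reaction	VIDH	1 CIT + 1 NAD -> 1 AKG + 1 CO2 + 1 NADH	0	aconitase + isocitrate dehydrogenase
reaction	VAKGDH	1 AKG + 1 NAD -> 1 SUCCOA + 1 CO2 + 1 NADH	0	alpha-ketoglutarate dehydrogenase
reaction	VSCS	1 SUCCOA + 1 ADP + 1 Pi -> 1 SUC + 1 ATP	0	succinyl-CoA synthetase
reaction	VSDH	1 SUC + 1 FAD <-> 1 FUM + 1 FADH2	1	succinate dehydrogenase
reaction	VFUM	1 FUM + 1 H2O <-> 1 MAL	1	fumarase
reaction	VMDH	1 MAL + 1 NAD <-> 1 OXA + 1 NADH	1	malate dehydrogenase
reaction	VME	1 MAL + 1 NAD -> 1 PYR + 1 CO2 + 1 NADH	0	malic enzyme
# --- lipogenesis ---
reaction	VACL	1 CIT + 1 ATP -> 1 ACCOAC + 1 OXA + 1 ADP + 1 Pi	0	ATP citrate lyase	HCIT:inhibit	hydroxycitrate target
reaction	VPALM	8 ACCOAC + 14 NADPH + 7 ATP -> 1 PALM + 14 NADP + 7 ADP + 7 Pi	0	fatty acid synthase (palmitate, lumped)
# --- oxidative phosphorylation & energy/redox housekeeping ---
reaction	Vresp	1 NADH + 0.5 O2 -> 1 NAD + 1 H2O	0	respiratory chain, NADH branch
reaction	VFADox	1 FADH2 + 0.5 O2 -> 1 FAD + 1 H2O	0	respiratory chain, FADH2 branch
reaction	VATPase	1 ADP + 1 Pi -> 1 ATP + 1 H2O	0	mitochondrial ATP synthase	METF:inhibit	metformin target
reaction	VNADleak	1 NAD ->	0	NAD+ leakage/degradation	METF:activate	metformin target
reaction	VAK	2 ADP <-> 1 ATP + 1 AMP	1	adenylate kinase
# --- amino acid metabolism ---
reaction	VGLNT	1 EGLN + 1 H2O -> 1 GLU + 1 NH4	0	glutaminase (GlnT, incl. transport)
reaction	VGLDH	1 GLU + 1 NAD + 1 H2O <-> 1 AKG + 1 NH4 + 1 NADH	1	glutamate dehydrogenase
reaction	VALATA	1 ALA + 1 AKG <-> 1 PYR + 1 GLU	1	alanine transaminase
reaction	VASPTA	1 ASP + 1 AKG <-> 1 OXA + 1 GLU	1	aspartate transaminase
reaction	VSERDH	1 SER -> 1 PYR + 1 NH4	0	serine dehydratase
reaction	VGLYC	1 GLY + 1 NAD -> 1 CO2 + 1 NH4 + 1 NADH	0	glycine cleavage system
reaction	VLEUTA	1 LEU + 1 AKG + 2 NAD -> 1 GLU + 3 ACCOA + 2 NADH	0	leucine degradation (ketogenic, lumped)
reaction	VILETA	1 ILE + 1 AKG + 2 NAD -> 1 GLU + 1 ACCOA + 1 SUCCOA + 2 NADH	0	isoleucine degradation (lumped)
reaction	VVALTA	1 VAL + 1 AKG + 2 NAD -> 1 GLU + 1 SUCCOA + 1 CO2 + 2 NADH	0	valine degradation (lumped)
reaction	VHISARGTA	1 HIS + 1 ARG + 2 H2O -> 2 GLU + 2 NH4 + 1 CO2	0	histidine/arginine transamination (lumped)
# --- biomass ---
reaction	Vgrowth	0.4 R5P + 0.05 PALM + 0.1 NADPH + 0.2 G6P + 0.3 GLU + 6.8 ATP + 0.02 LYS + 0.02 THR + 0.02 TYR + 0.02 ASN + 0.02 EGLU + 0.02 GLY -> 0.1 NADP + 6.8 ADP + 6.8 Pi	0	biomass synthesis (amino acids, intermediates, palmitate, nucleotides; 6.8 ATP/unit polymerization cost)		biomass target reaction
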