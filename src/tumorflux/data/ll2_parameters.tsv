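# Calibrated kinetic parameters for the packaged LL/2 central-carbon-metabolism
# model.  vmax values are back-solved so that, at the reference state (the
# "init"/"inlet" concentrations below), the flux vector equals a balanced
# Warburg-style steady-state distribution (S_m v = 0, lactate secretion
# carrying ~70% of glycolytic pyruvate).
# Record types:
#   rate  <tab> reaction_id <tab> vmax <tab> vmax_rev <tab> km pairs (id:mM;...)
#   drug  <tab> drug_id <tab> target_reaction <tab> mode <tab> k_half_mM
#   inlet <tab> species <tab> mM     (C0 at the tumor inlet)
#   init  <tab> species <tab> mM     (intracellular m at t0)
#   cinit <tab> species <tab> mM     (blood C at t0 where it differs from C0)
# km entries may name kinetic effectors absent from the stoichiometry
# (e.g. NADH drives the ATP synthase).
rate	VHK	0.0315	0	EGLC:2.75;ATP:0.125
rate	VPGI	0.0255	0	G6P:0.1
rate	VPFK	0.026775	0	F6P:0.05;ATP:0.125
rate	VGAPDH	0.0819315	0	GAP:0.025;Pi:0.75;ADP:0.0125;NAD:0.02
rate	VPK	0.05355	0	PEP:0.01;ADP:0.0125
rate	VLDH	0.323908	0.0286568	PYR:0.2;NADH:0.3;LAC:1;NAD:0.001
rate	VG6PDH	0.00315	0	G6P:0.1;NADP:0.001
rate	VPDH	0.00918	0	PYR:0.05;NAD:0.02
rate	VPC	0.000819	0	PYR:0.05;ATP:0.125;CO2:1
rate	VCS	0.0180036	0	ACCOA:0.025;OXA:0.005;H2O:10
rate	VIDH	0.00918	0	CIT:0.15;NAD:0.02
rate	VAKGDH	0.008262	0	AKG:0.1;NAD:0.02
rate	VSCS	0.01512	0	SUCCOA:0.025;ADP:0.0125;Pi:0.75
rate	VSDH	0.0112	0.00112	SUC:0.25;FAD:0.0025;FUM:0.05;FADH2:0.0005
rate	VFUM	0.0106688	0.00106667	FUM:0.05;MAL:0.15;H2O:10
rate	VMDH	0.00765	0.0007875	MAL:0.15;NAD:0.02;OXA:0.005;NADH:0.0125
rate	VME	0.002907	0	MAL:0.15;NAD:0.02
rate	VACL	0.00315	0	CIT:0.15;ATP:0.125
rate	VPALM	0.000413438	0	ACCOAC:0.01;NADPH:0.005;ATP:0.125
rate	Vresp	0.100127	0	NADH:0.5;O2:0.02
rate	VFADox	0.01008	0	FADH2:0.0005;O2:4.4
rate	VATPase	0.00140569	0	ADP:0.0125;Pi:0.75;NADH:0.0125
rate	VNADleak	0.00033	0	NAD:0.1
rate	VAK	0.00525	0.0055125	ADP:0.0125;ATP:0.125;AMP:0.0025
rate	VGLNT	0.00075015	0	EGLN:0.35;H2O:10
rate	VGLDH	0.00497349	0.00102375	GLU:0.5;NAD:0.02;AKG:0.1;NH4:0.025;NADH:0.0125;H2O:10
rate	VALATA	0.01125	0.0050625	ALA:0.2;AKG:0.1;PYR:0.05;GLU:0.5
rate	VASPTA	0.0028125	0.000421875	ASP:0.01;AKG:0.1;OXA:0.005;GLU:0.5
rate	VSERDH	0.00075	0	SER:0.075
rate	VGLYC	0.000765	0	GLY:0.15;NAD:0.02
rate	VLEUTA	0.0011475	0	LEU:0.075;AKG:0.1;NAD:0.02
rate	VILETA	0.0011475	0	ILE:0.05;AKG:0.1;NAD:0.02
rate	VVALTA	0.0011475	0	VAL:0.125;AKG:0.1;NAD:0.02
rate	VHISARGTA	0.00045009	0	HIS:0.04;ARG:0.075;H2O:10
rate	Vgrowth	0.227056	0	R5P:0.025;PALM:0.025;GLU:0.5;ATP:0.125;G6P:0.1;LYS:0.15;THR:0.1;TYR:0.04;ASN:0.025;EGLU:0.025;GLY:0.15
drug	DICLO	VHK	inhibit	0.5
drug	DICLO	VLDH	inhibit	0.01
drug	LA	VPDH	activate	0.05
drug	HCIT	VACL	inhibit	0.1
drug	METF	VATPase	inhibit	0.05
drug	METF	VNADleak	activate	0.05
inlet	EGLC	5.5
inlet	EGLN	0.7
inlet	EGLU	0.05
inlet	LAC	1.5
inlet	ALA	0.4
inlet	ARG	0.15
inlet	ASN	0.05
inlet	ASP	0.02
inlet	GLY	0.3
inlet	HIS	0.08
inlet	ILE	0.1
inlet	LEU	0.15
inlet	LYS	0.3
inlet	SER	0.15
inlet	THR	0.2
inlet	TYR	0.08
inlet	VAL	0.25
inlet	NH4	0.05
inlet	CO2	25.0
inlet	H2O	50000.0
inlet	O2	8.8
inlet	Pi	1.5
init	G6P	0.2
init	F6P	0.1
init	GAP	0.05
init	PEP	0.02
init	PYR	0.1
init	R5P	0.05
init	ACCOA	0.05
init	ACCOAC	0.02
init	CIT	0.3
init	AKG	0.2
init	SUCCOA	0.05
init	SUC	0.5
init	FUM	0.1
init	MAL	0.3
init	OXA	0.01
init	PALM	0.05
init	GLU	4.0
init	ATP	2.5
init	ADP	0.25
init	AMP	0.05
init	NAD	1.0
init	NADH	0.25
init	NADP	0.02
init	NADPH	0.1
init	FAD	0.05
init	FADH2	0.01
cinit	LAC	4.0
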