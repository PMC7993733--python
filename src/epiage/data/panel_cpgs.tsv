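marker	label	genomic_pos	amplicon_offset	array_id	synthetic
FHL2	C1	105399282	32	cg06639320	0
FHL2	C2	105399287	37		1
FHL2	C3	105399297	47		1
FHL2	C4	105399307	57		1
FHL2	C5	105399317	67		1
FHL2	C6	105399327	77		1
FHL2	C7	105399337	87		1
FHL2	C8	105399347	97		1
FHL2	C9	105399357	107		1
FHL2	C10	105399367	117		1
KLF14	C1	130734355	48	cg14361627	0
KLF14	C2	130734352	45		1
KLF14	C3	130734372	65		0
KLF14	C4	130734375	68		0
TRIM59	C1	160450168	28		1
TRIM59	C2	160450178	38		1
TRIM59	C3	160450188	48		1
TRIM59	C4	160450198	58		1
TRIM59	C5	160450213	73		1
TRIM59	C6	160450223	83		1
TRIM59	C7	160450233	93		1
TRIM59	C8	160450202	62		0
ELOVL2	C1	11044536	36		1
ELOVL2	C2	11044655	155	cg24724428	0
ELOVL2	C3	11044565	65		1
ELOVL2	C4	11044594	94		1
ELOVL2	C5	11044623	123		1
ELOVL2	C6	11044667	167		1
ELOVL2	C7	11044634	134		0
ELOVL2	C8	11044696	196		1
ELOVL2	C9	11044628	128		0
MIR29B2CHG	C1	207823681	76		0
MIR29B2CHG	C2	207823653	48		1
MIR29B2CHG	C3	207823672	67		0
EDARADD	C1	236394383	118	cg09809672	0
EDARADD	C2	236394439	62		1
ASPA	C1	3476273	66	cg02228185	0
PDE4C	C1	18232990	37		1
PDE4C	C2	18233019	66		1
PDE4C	C3	18233048	95		1
PDE4C	C4	18233105	152		0
PDE4C	C5	18233127	174		0
PDE4C	C6	18233131	178	cg01481989	0
PDE4C	C7	18233077	124		1
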