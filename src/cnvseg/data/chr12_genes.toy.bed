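# Toy/synthetic gene annotation for chromosome 12 (demo + tests only).
# Each gene carries the coordinates of the region-table interval containing
# it, not its true transcript coordinates; this is a constructed stand-in,
# not a real annotation.
chr12	55311005	55381000	BAZ2A
chr12	55311005	55381000	ATP5B
chr12	55311005	55381000	PTGES3
chr12	55945618	55983227	R3HDM2
chr12	56081247	56403704	INHBC
chr12	56081247	56403704	INHBE
chr12	56081247	56403704	GLI1
chr12	56081247	56403704	ARHGAP9
chr12	56081247	56403704	MARS
chr12	56081247	56403704	DDIT3
chr12	56081247	56403704	MBD6
chr12	56081247	56403704	DCTN2
chr12	56081247	56403704	KIF5A
chr12	56081247	56403704	PIP5K2C
chr12	56081247	56403704	DTX3
chr12	56081247	56403704	GEFT
chr12	56081247	56403704	SLC26A10
chr12	56081247	56403704	B4GALNT1
chr12	56081247	56403704	OS9
chr12	56403703	56424571	CENTG1
chr12	56424570	56529132	TSPAN31
chr12	56424570	56529132	CDK4
chr12	56424570	56529132	CYP27B1
chr12	56424570	56529132	METTL1
chr12	56424570	56529132	TSFM
chr12	56424570	56529132	AVIL
chr12	56424570	56529132	CTDSP2
chr12	47781997	47789120	LMBR1L
chr12	56595121	56725516	XRCC6BP1
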