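residue_name	atom_name	radius	well_depth	charge	hbond_class
*	element:C	1.908	0.086	0.0	none
*	element:N	1.824	0.170	0.0	none
*	element:O	1.661	0.210	0.0	none
*	element:S	2.000	0.250	0.0	none
*	element:P	2.100	0.200	0.0	none
*	element:H	0.600	0.0157	0.0	none
*	element:*	1.800	0.100	0.0	none
*	N	.	.	0.0	donor
*	O	.	.	0.0	acceptor
*	OXT	.	.	0.0	acceptor
PRO	N	.	.	0.0	none
SER	OG	.	.	0.0	both
THR	OG1	.	.	0.0	both
TYR	OH	.	.	0.0	both
ASN	OD1	.	.	0.0	acceptor
ASN	ND2	.	.	0.0	donor
GLN	OE1	.	.	0.0	acceptor
GLN	NE2	.	.	0.0	donor
ASP	OD1	.	.	-0.5	acceptor
ASP	OD2	.	.	-0.5	acceptor
GLU	OE1	.	.	-0.5	acceptor
GLU	OE2	.	.	-0.5	acceptor
LYS	NZ	.	.	1.0	donor
ARG	NE	.	.	0.0	donor
ARG	NH1	.	.	0.5	donor
ARG	NH2	.	.	0.5	donor
HIS	ND1	.	.	0.0	both
HIS	NE2	.	.	0.0	both
TRP	NE1	.	.	0.0	donor
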