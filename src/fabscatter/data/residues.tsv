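# Atomic composition of the 20 standard amino-acid residues as they occur
# inside a polypeptide chain (free amino acid minus one water per peptide
# bond), neutral protonation states, His singly protonated at N-epsilon.
# residue	H	C	N	O	S
GLY	3	2	1	1	0
ALA	5	3	1	1	0
SER	5	3	1	2	0
CYS	5	3	1	1	1
THR	7	4	1	2	0
VAL	9	5	1	1	0
LEU	11	6	1	1	0
ILE	11	6	1	1	0
PRO	7	5	1	1	0
MET	9	5	1	1	1
PHE	9	9	1	1	0
TYR	9	9	1	2	0
TRP	10	11	2	1	0
ASP	5	4	1	3	0
GLU	7	5	1	3	0
ASN	6	4	2	2	0
GLN	8	5	2	2	0
HIS	7	6	3	1	0
LYS	12	6	2	1	0
ARG	12	6	4	1	0
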