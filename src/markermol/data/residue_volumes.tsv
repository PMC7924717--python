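# Mean residue volumes (A^3) for the 20 canonical amino acids
# (Zamyatnin-type consensus values from protein crystal packing).
# Users may substitute their own table via coarse.load_volume_table().
ALA	88.6
ARG	173.4
ASN	114.1
ASP	111.1
CYS	108.5
GLN	143.8
GLU	138.4
GLY	60.1
HIS	153.2
ILE	166.7
LEU	166.7
LYS	168.6
MET	162.9
PHE	189.9
PRO	112.7
SER	89.0
THR	116.1
TRP	227.8
TYR	193.6
VAL	140.0
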