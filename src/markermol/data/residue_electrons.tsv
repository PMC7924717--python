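# Electron counts per residue (in-chain, neutral form), for the optional
# electron-count scattering-weight mode of the residue-grained Debye sum.
ALA	38
ARG	84
ASN	60
ASP	60
CYS	54
GLN	68
GLU	68
GLY	30
HIS	72
ILE	62
LEU	62
LYS	70
MET	70
PHE	78
PRO	52
SER	46
THR	54
TRP	98
TYR	86
VAL	54
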