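# pepshift random-coil reference shifts, version 1
# Residue-type random-coil chemical shifts (ppm) for backbone nuclei,
# compiled from standard literature coil tables (Wishart-style statistical
# coil values at neutral pH, ~298 K). Neighbor/temperature/pH corrections
# are not included; they default to zero in RandomCoilModel.
residue_name,atom_name,shift_ppm
ALA,H,8.24
ALA,HA,4.32
ALA,N,123.8
ALA,CA,52.5
ALA,CB,19.1
ARG,H,8.23
ARG,HA,4.34
ARG,N,120.5
ARG,CA,56.0
ARG,CB,30.9
ASN,H,8.40
ASN,HA,4.74
ASN,N,118.7
ASN,CA,53.1
ASN,CB,38.9
ASP,H,8.34
ASP,HA,4.64
ASP,N,120.4
ASP,CA,54.2
ASP,CB,41.1
CYS,H,8.32
CYS,HA,4.55
CYS,N,118.8
CYS,CA,58.2
CYS,CB,28.0
GLN,H,8.32
GLN,HA,4.34
GLN,N,119.8
GLN,CA,55.7
GLN,CB,29.4
GLU,H,8.42
GLU,HA,4.35
GLU,N,120.2
GLU,CA,56.6
GLU,CB,29.9
GLY,H,8.33
GLY,HA,3.96
GLY,N,108.8
GLY,CA,45.1
HIS,H,8.42
HIS,HA,4.73
HIS,N,118.2
HIS,CA,55.0
HIS,CB,29.0
ILE,H,8.00
ILE,HA,4.17
ILE,N,119.9
ILE,CA,61.1
ILE,CB,38.8
LEU,H,8.16
LEU,HA,4.34
LEU,N,121.8
LEU,CA,55.1
LEU,CB,42.4
LYS,H,8.29
LYS,HA,4.32
LYS,N,120.4
LYS,CA,56.2
LYS,CB,33.1
MET,H,8.28
MET,HA,4.48
MET,N,119.6
MET,CA,55.4
MET,CB,32.9
PHE,H,8.30
PHE,HA,4.62
PHE,N,120.3
PHE,CA,57.7
PHE,CB,39.6
PRO,HA,4.42
PRO,CA,63.3
PRO,CB,32.1
PRO,CG,27.2
SER,H,8.31
SER,HA,4.47
SER,N,115.7
SER,CA,58.3
SER,CB,63.8
THR,H,8.15
THR,HA,4.35
THR,N,113.6
THR,CA,61.8
THR,CB,69.8
TRP,H,8.25
TRP,HA,4.66
TRP,N,121.3
TRP,CA,57.5
TRP,CB,29.6
TYR,H,8.12
TYR,HA,4.55
TYR,N,120.3
TYR,CA,57.9
TYR,CB,38.8
VAL,H,8.03
VAL,HA,4.12
VAL,N,119.2
VAL,CA,62.2
VAL,CB,32.9
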