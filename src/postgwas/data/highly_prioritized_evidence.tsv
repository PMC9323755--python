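gene	sources
TRIOBP	NS,MX,SMR,DEPICT
USP36	NS,MX,SMR,DEPICT
LRIG1	NS,MX,SMR,DEPICT
PRR14	NS,MX,SMR,DEPICT
SENP2	NS,MX,SMR,DEPICT
PPL	NS,MX,SMR,DEPICT,3xSMR
MLXIP	NS,MX,SMR,DEPICT
ITGA9	NS,MX,SMR,DEPICT,3xSMR
YAF2	MX,SMR,DEPICT,3xSMR
LNPEP	MX,SMR,DEPICT,3xSMR
SLC39A1	MX,SMR,DEPICT,3xSMR
MAPKAP1	MX,SMR,DEPICT,3xSMR
TP53INP1	MX,SMR,DEPICT,3xSMR
MAK16	NS,MX,SMR,3xSMR
ERAP2	ML,MX,SMR,3xSMR
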