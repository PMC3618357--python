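Seven-locus microsatellite panel
SCA30
SM3
SM37
SCA47
SCA49
90RTE
SCA8
POP
d01 ,  001002 003003 001004 002002 001003 001001 005006
d02 ,  002002 001003 000000 001002 002003 001002 005005
POP
d03 ,  001001 002002 004004 002003 001001 002002 006006
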