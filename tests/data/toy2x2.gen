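Toy two-individual, two-locus file
locA
locB
POP
ind1 ,  001002 003003
ind2 ,  001001 000000
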