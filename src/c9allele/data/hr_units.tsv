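haplotype	kind	units	modal	lo	hi
K	fixed	2			
F	fixed	2			
Q	fixed	2			
N	fixed	4			
P	fixed	5			
J	variable		6	5	7
R	variable		8	7	16
Z	undetermined				
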