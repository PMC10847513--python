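codon	count
AAA	300
AAC	700
AAG	700
AAT	300
ACA	300
ACC	700
ACG	700
ACT	300
AGA	300
AGC	700
AGG	700
AGT	300
ATA	300
ATC	700
ATG	700
ATT	300
CAA	300
CAC	700
CAG	700
CAT	300
CCA	300
CCC	700
CCG	700
CCT	300
CGA	300
CGC	700
CGG	700
CGT	300
CTA	300
CTC	700
CTG	700
CTT	300
GAA	300
GAC	700
GAG	700
GAT	300
GCA	300
GCC	700
GCG	700
GCT	300
GGA	300
GGC	700
GGG	700
GGT	300
GTA	300
GTC	700
GTG	700
GTT	300
TAC	700
TAT	300
TCA	300
TCC	700
TCG	700
TCT	300
TGC	700
TGG	700
TGT	300
TTA	300
TTC	700
TTG	700
TTT	300
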