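codon	count
AAA	600
AAC	400
AAG	400
AAT	600
ACA	600
ACC	400
ACG	400
ACT	600
AGA	600
AGC	400
AGG	400
AGT	600
ATA	600
ATC	400
ATG	400
ATT	600
CAA	600
CAC	400
CAG	400
CAT	600
CCA	600
CCC	400
CCG	400
CCT	600
CGA	600
CGC	400
CGG	400
CGT	600
CTA	600
CTC	400
CTG	400
CTT	600
GAA	600
GAC	400
GAG	400
GAT	600
GCA	600
GCC	400
GCG	400
GCT	600
GGA	600
GGC	400
GGG	400
GGT	600
GTA	600
GTC	400
GTG	400
GTT	600
TAC	400
TAT	600
TCA	600
TCC	400
TCG	400
TCT	600
TGC	400
TGG	400
TGT	600
TTA	600
TTC	400
TTG	400
TTT	600
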