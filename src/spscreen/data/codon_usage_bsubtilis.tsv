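# Genome-wide B. subtilis-style codon usage (frequency per 1000 codons).
# Default reference for RSCU/CAI weights and most-frequent-codon
# retro-translation; replaceable via config.
TTT	30.6
TTC	14.4
TTA	19.3
TTG	15.5
CTT	23.3
CTC	10.9
CTA	4.9
CTG	23.0
ATT	36.8
ATC	27.0
ATA	9.3
ATG	27.0
GTT	19.2
GTC	17.5
GTA	13.2
GTG	17.7
TCT	12.9
TCC	8.1
TCA	14.8
TCG	6.4
AGT	6.7
AGC	14.3
CCT	10.5
CCC	3.3
CCA	6.9
CCG	16.1
ACT	8.7
ACC	8.5
ACA	22.2
ACG	14.7
GCT	18.8
GCC	16.1
GCA	21.6
GCG	20.2
TAT	22.6
TAC	12.0
TAA	0.6
TAG	0.2
TGA	0.1
CAT	15.2
CAC	7.5
CAA	19.8
CAG	18.7
AAT	22.1
AAC	17.3
AAA	49.1
AAG	21.1
GAT	33.0
GAC	18.8
GAA	48.5
GAG	23.1
TGT	3.6
TGC	4.4
TGG	10.3
CGT	7.6
CGC	8.6
CGA	4.1
CGG	6.5
AGA	10.9
AGG	3.9
GGT	12.7
GGC	23.2
GGA	21.7
GGG	11.3
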