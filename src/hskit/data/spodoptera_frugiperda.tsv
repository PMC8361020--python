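codon	freq_per_thousand
TGT	8.5
TGC	13.2
GAA	27.6
GAG	33.1
TTT	10.1
TTC	27.5
CAT	8.7
CAC	15.6
AAA	26.8
AAG	49.2
AAT	13.4
AAC	28.8
CAA	16.1
CAG	21.6
TAT	10.0
TAC	24.4
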