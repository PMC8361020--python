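codon	freq_per_thousand
TGT	6.2
TGC	12.4
GAA	21.6
GAG	38.6
TTT	13.1
TTC	22.4
CAT	11.3
CAC	13.8
AAA	16.0
AAG	32.3
AAT	15.1
AAC	18.5
CAA	13.5
CAG	20.8
TAT	10.0
TAC	15.1
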