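codon	freq_per_thousand
TGT	9.8
TGC	7.2
GAA	36.0
GAG	29.4
TTT	25.1
TTC	18.0
CAT	13.4
CAC	8.7
AAA	32.6
AAG	33.5
AAT	28.0
AAC	17.9
CAA	20.7
CAG	15.0
TAT	17.8
TAC	13.5
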