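codon	freq_per_thousand
TGT	7.0
TGC	9.8
GAA	24.1
GAG	37.4
TTT	17.2
TTC	23.6
CAT	11.1
CAC	11.6
AAA	18.9
AAG	34.7
AAT	17.8
AAC	20.4
CAA	16.7
CAG	22.0
TAT	10.5
TAC	17.2
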