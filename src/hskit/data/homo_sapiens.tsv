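codon	freq_per_thousand
TGT	10.6
TGC	12.6
GAA	29.0
GAG	39.6
TTT	17.6
TTC	20.3
CAT	10.9
CAC	15.1
AAA	24.4
AAG	31.9
AAT	17.0
AAC	19.1
CAA	12.3
CAG	34.2
TAT	12.2
TAC	15.3
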