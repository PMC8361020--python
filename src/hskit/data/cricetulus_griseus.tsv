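codon	freq_per_thousand
TGT	9.1
TGC	10.3
GAA	28.4
GAG	41.1
TTT	19.6
TTC	22.0
CAT	10.2
CAC	12.9
AAA	24.6
AAG	38.4
AAT	17.4
AAC	21.2
CAA	10.3
CAG	33.4
TAT	13.1
TAC	16.4
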