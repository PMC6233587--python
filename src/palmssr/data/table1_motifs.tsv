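motif_type	count	percent
di	15	3.59
tri	380	90.91
hexa	15	3.59
compound	19	4.55
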