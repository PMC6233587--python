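species	amplified	total
Acrocomia_intumescens	144	145
Acrocomia_totai	143	145
Elaeis_guineensis	117	145
Bactris_gasipaes	117	145
Euterpe_edulis	102	145
Sabal_causiarum	104	145
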