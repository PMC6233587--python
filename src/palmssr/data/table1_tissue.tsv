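category	count	percent
flower	23	5.50
fruit	28	6.70
vegetative	63	15.07
vegetative/flower	60	14.35
vegetative/fruit	21	5.02
flower/fruit	19	4.55
vegetative/flower/fruit	204	48.80
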