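chain_a	res_a	chain_b	res_b	target	k
A	32	B	428	3.5	10.0
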