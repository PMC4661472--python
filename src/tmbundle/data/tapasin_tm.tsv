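helix_id	chain_id	start_res	end_res	sequence
TPN	B	417	433	FLLLFGAVGLLKVLLWA
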