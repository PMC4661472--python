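helix_id	chain_id	start_res	end_res	sequence
TM1	A	20	44	LAWLGTVLLLLADWVLLRTALPRIF
TM2	A	57	76	VWAVGLSRWAVLWLGACGVL
TM3	A	96	123	LKPLAAALGLALPGLALFRELISWGAPG
TM4	A	137	160	PTAFVVSYAAALPAAALWHKLGSL
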