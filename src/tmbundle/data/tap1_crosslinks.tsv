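residue	dimer_formed	blocked_by_tapasin	note
31	0	0	no dimer
32	0	0	no dimer; interaction hub
33	1	1	blocked by partner
34	1	1	blocked by partner
67	1	1	blocked by partner
68	1	1	blocked by partner
69	1	1	blocked by partner
70	1	1	blocked by partner
106	1	0	inferred position
107	1	1	blocked by partner
108	0	NA	proline; aggregates on oxidation; excluded from scoring
109	1	0	inferred position
147	1	0	inferred position
148	1	0	inferred position
149	0	NA	proline; aggregates on oxidation; excluded from scoring
150	1	0	inferred position
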