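loop_id	chain	start	end	n_residues
6	A	138	148	11
8	A	185	192	8
13	A	245	257	13
15	A	278	287	10
17	A	331	337	7
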