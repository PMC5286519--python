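start_res	sequence	type
139	RPGH	II
246	IIGF	II
251	SPNK	I
252	PNKA	I
254	KAGT	II
282	APFE	II
334	PSDF	I
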