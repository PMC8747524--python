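marker	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16	17	18	19	20	r2_printed
CIR6-M1	hh	ll	ll	ll	hh	hh	hh	hh	hh	hh	ll	ll	hl	hl	ll	hl	ll	ll	ll	ll	0.722
CIR6-M2	hh	ll	ll	ll	hh	hh	hh	hh	hh	hh	hh	ll	hl	hl	hl	hh	hl	ll	ll	ll	0.461
CIR6-M3	hh	ll	ll	ll	hh	hh	hh	hh	hh	hh	hh	ll	hl	hl	hl	hh	hl	ll	ll	ll	0.461
CIR6-M4	hh	ll	ll	ll	hh	hh	hh	hh	hh	hh	ll	ll	hl	hl	ll	hl	ll	ll	ll	ll	0.722
CIR6-M5	hh	ll	ll	ll	hh	hh	hh	hh	hh	hh	hh	ll	hl	hl	hl	hh	hl	ll	ll	ll	0.461
CIR6-M6	hh	ll	ll	ll	hh	hh	hh	hh	hh	hh	hh	ll	hl	hl	hl	hh	hl	ll	ll	ll	0.461
CIR6-M7	hh	ll	ll	ll	hh	hh	hh	hh	hh	hh	hh	ll	hl	hl	hl	hh	hl	ll	hl	ll	0.446
CIR6-M8	hh	ll	ll	ll	hh	hh	hh	hh	hh	hh	hh	ll	hl	ll	hl	hh	ll	ll	hl	ll	0.472
CIR9-M1	hh	ll	ll	ll	hh	ll	hh	hh	hh	hh	hh	ll	hl	hh	hl	hh	hl	ll	hl	ll	0.316
CIR9-M2	hh	ll	ll	ll	hh	ll	hh	hh	hh	hh	ll	ll	hl	hh	hl	hl	hh	hl	m	hh	0.295
CIR9-M3	hh	ll	ll	ll	hh	ll	hh	hh	hh	ll	ll	ll	hl	hh	ll	ll	ll	hh	hl	ll	0.284
CIR9-M4	hh	ll	ll	ll	hh	ll	hh	hh	hh	ll	ll	ll	hl	hh	ll	ll	ll	ll	ll	ll	0.480
CIR9-M5	hh	ll	ll	ll	hh	ll	hh	hh	hh	hh	ll	ll	hl	hh	hl	hl	ll	hl	hl	hl	0.449
CIR9-M6	hh	ll	ll	ll	hh	ll	hh	hh	hh	ll	ll	ll	hl	hh	hl	ll	ll	hl	hl	hh	0.268
CIR9-M7	hh	ll	ll	ll	hl	ll	hh	hh	hh	ll	ll	ll	hl	hh	hl	ll	ll	hl	hl	hh	0.226
CIR9-M8	hh	ll	ll	ll	hh	ll	hh	hh	hh	hh	hh	ll	hl	hh	hh	hh	hl	hl	hh	hh	0.149
CIR9-M9	hh	ll	ll	ll	hh	ll	hh	hh	hl	hh	hl	ll	ll	hh	hl	hh	hl	ll	hl	ll	0.258
CIR9-M10	hh	ll	ll	ll	hh	ll	hh	hh	hh	ll	hh	ll	hl	hh	hl	hl	hl	ll	ll	ll	0.269
CIR9-M11	hh	ll	ll	ll	hh	ll	hh	hh	hh	hh	hh	ll	hl	hh	hl	hh	hl	ll	hl	ll	0.316
CIR9-M12	hh	ll	ll	ll	hh	ll	hh	hh	hh	hh	m	ll	hl	hh	hl	hh	hl	ll	hl	ll	0.356
CIR9-M13	hh	ll	ll	ll	hh	ll	hh	hh	hh	hh	hh	ll	hl	hh	hl	hh	hl	ll	hl	ll	0.316
CIR10-M1	hh	ll	ll	ll	hh	ll	hh	hh	hh	ll	ll	ll	hl	hh	ll	ll	ll	ll	hh	ll	0.356
CIR10-M2	hh	ll	ll	ll	hh	ll	hh	hh	hh	ll	hh	ll	hl	hh	hl	hl	hl	ll	hh	ll	0.193
CIR10-M3	hh	ll	ll	ll	d	ll	ll	d	d	ll	ll	ll	d	d	ll	ll	ll	ll	d	ll	-
CIR10-M4	hh	ll	ll	ll	d	ll	d	d	d	ll	ll	ll	d	d	ll	ll	ll	ll	d	ll	-
CIR10-M5	hh	ll	ll	ll	hh	ll	hh	hh	hh	ll	ll	ll	hl	hh	ll	ll	hl	m	hh	m	0.329
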