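species	element	start_offset	end_offset
mouse	A	1	7
mouse	AB	8	10
mouse	B	11	20
mouse	BC	21	23
mouse	C	24	31
mouse	CD	32	38
mouse	D	39	45
mouse	DE	46	48
mouse	E	49	55
mouse	EF	56	69
mouse	F	70	79
mouse	FG	80	86
mouse	G	87	91
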