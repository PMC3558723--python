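species	element	start_offset	end_offset
human	A	1	7
human	AB	8	10
human	B	11	20
human	BC	21	23
human	C	24	31
human	CD	32	38
human	D	39	45
human	DE	46	48
human	E	49	55
human	EF	56	63
human	F	64	73
human	FG	74	78
human	G	79	85
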