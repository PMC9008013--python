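# name	iupac	core_mask (1 = core position)
cenpb_canonical	YTTCGTTGGAARCGGGA	01111000010011110
cenpb_consensus	NTTCGNNNNANNCGGGN	01111000010011110
cenpb_element	AAACGGG	1111111
bovine_proposed	YTCCAGWYRARGCAGGR	01111000010011110
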