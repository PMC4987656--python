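gene	locus	targeting	copy_label	printed_side
ppc	3ABDL			C4
ppc	5ABDL			C3
aat	3ABDL	cyt	aat1	C4
aat	7ABDL	mt	aat2	C4
aat	1ABDL			C3
aat	6ABDL			C3
aat	6ABDS			C3
aat	7ADS4AL			C3
mdh	5ABDS	mt	mdh2	C4
mdh	1ABDL	cyt	mdh1	C3
me2	2ABDS	mt		C4
me2	1ABDS	plastid		C3
gpt	2ABDS	cyt		C4
gpt	5ABDS	cyt		C4
ppdk	1ABDL	cp		C4
ppdk	1ABDL	cyt		C3
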