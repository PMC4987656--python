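table	species	location	window	printed_label
2	Brachypodium distachyon	1	LEGDPYLKQRLRLRDPY	C3
2	Brachypodium distachyon	2	LESDPYLRQRLMLRDSY	C3
2	Brachypodium distachyon	2	LEGDPYLRQRLRLRE??	C3
2	Brachypodium distachyon	3	LEGDPYLKQRLRLRESY	C3
2	Brachypodium distachyon	4	LEGDPYLKQRLRLRDAY	C3
2	Hordeum vulgare	3	LESDPYLRQRLMLRDSY	C3
2	Hordeum vulgare	3	LEGDPYLRQSLRLRDSY	C4?
2	Hordeum vulgare	5	LEGDPYLKQRLRLRDAY	C3
2	Hordeum vulgare	6	LEGDPYLKQRLRLRESY	C3
2	Hordeum vulgare	7	LEDDPYLKQRLRLRDPY	C3
2	A. sha, spe, tau; T. mon, ura; T. durum (cappelli)	3?	LESDPYLRQRLLLRDSY	C3
2	A. sha, spe, tau; T. mon, ura; T. durum (cappelli)	3?	LEGDPYLRQSLRLRDSY	C4?
2	A. sha, spe, tau; T. mon, ura; T. durum (cappelli)	5?	LEGDPYLKQRLRLRDAY	C3
2	A. sha, spe, tau; T. mon, ura; T. durum (cappelli)	6?	LEGDPYLKQRLRLRESY	C3
2	A. sha, spe, tau; T. mon, ura; T. durum (cappelli)	7?	LEDDPYLKQRLRLRDPY	C3
2	T. durum (strongfield)	3?	LESDPYLRQRLLLRDSY	C3
2	T. durum (strongfield)	3?	LEGDPYLRQSLRLRDSY	C4?
2	T. durum (strongfield)	6?	LEGDPYLKQRLRLRESY	C3
2	T. durum (strongfield)	7?	LEDDPYLKQRLRLRDPY	C3
2	T. aestivum	3S	LESDPYLRQRLLLRDSY	C3
2	T. aestivum	3L	LEGDPYLRQSLRLRDSY	C4?
2	T. aestivum	5L	LEGDPYLKQRLRLRDAY	C3
2	T. aestivum	6ASBDL	LEGDPYLKQRLRLRESY	C3
2	T. aestivum	7DL	LEDDPYLK?????????	
2	T. aestivum	4DS	LEGDPYLRQRLQLRDPY	C3
3	Physcomitrella patens	Bryophytes	LQGNPTLKQRLRLREPY	C3
3	Physcomitrella patens	Bryophytes	LQGNPSLKQRLRLREPY	C3
3	Physcomitrella patens	Bryophytes	LQGNPTLKQRLRLREPV	C3
3	Physcomitrella patens	Bryophytes	LEGNPTLKQRLRLREQY	C3
3	Selaginella moellendorffii	Lycophytes	LAGNPILKQRLSLREPF	C3
3	Selaginella moellendorffii	Lycophytes	LEENPTLKQRLRLREPF	C3
3	PA, AS, GG, JC, PS, TB	Gymnosperm	LEGDPYLKQRLRLRDSY	C3
3	Amborella trichopoda	Basal Angiosperm	LEGDPYLKQRLRLRDSY	C3
3	Oryza sativa	Oryzoideae (BOP clade)	LEGDLYLKQRLRLRNAY	C3
3	Oryza sativa	Oryzoideae (BOP clade)	LEGDPYLRQRLRIRDSY	C3
3	Oryza sativa	Oryzoideae (BOP clade)	LEGDPYLKQRLRLRDAY	C3
3	Oryza sativa	Oryzoideae (BOP clade)	LEGDPYLKQRLRLRESY	C3
3	Guadua sp.	Bambusoideae (BOP clade)	LEGDPYLKQRLRLRESY	C3
3	Guadua sp.	Bambusoideae (BOP clade)	LESDPYLRQRLMLRDSY	C3
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGDPYLKEGLRLRNPY	C4
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGDPYLKQQLRLRDPY	C4
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGSPGLKQRLRLRDPY	C3
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGDPYLKQRLRLRESY	C3
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGDPYLKQRLRIRDSY	C3
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGDPYLKQRLRLRDAY	C3
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGGPYLKQRLRLRDPY	C3
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGDLYLKQRLRLRDAY	C3
3	Alloteropsis spp.	Panicoideae (PACMAD clade)	LEGDPYLKQRLRLRDPY	C3
3	Panicum spp.	Panicoideae (PACMAD clade)	LEGDPFLKQSLRLRNPY	C4
3	Panicum spp.	Panicoideae (PACMAD clade)	LEGDPYLKQGLRLRNPY	C4
3	Panicum spp.	Panicoideae (PACMAD clade)	LEADPFLKQSLRLRNPY	C4
3	Panicum spp.	Panicoideae (PACMAD clade)	LEGDLYLKQRLRLRDAY	C3
3	Panicum spp.	Panicoideae (PACMAD clade)	LEGDPYLKQRLRLRDPY	C3
3	Setaria italica	Panicoideae (PACMAD)	LESDPGLKQQLRLRDPY	C4
3	Setaria italica	Panicoideae (PACMAD)	LEGDPYLKQRLRLRESY	C3
3	Setaria italica	Panicoideae (PACMAD)	LESDPGLQQQLMLRDSY	C3
3	Setaria italica	Panicoideae (PACMAD)	LEGDLYLKQRLRLRDAY	C3
3	Setaria italica	Panicoideae (PACMAD)	LEGDPYLKQRLRIRDSY	C3
3	Zea mays	Panicoideae (PACMAD)	LEGDPFLKQGLVLRNPY	C4
3	Zea mays	Panicoideae (PACMAD)	LEGDLYLKQRLRLRDAY	C3
3	Zea mays	Panicoideae (PACMAD)	LEGDPYLKQRLRIRDSY	C3
3	Zea mays	Panicoideae (PACMAD)	LEGDPYLKQRLRLRESY	C3
3	Sorghum bicolor	Panicoideae (PACMAD)	LEGDPYLKQGLRLRNPY	C4
3	Sorghum bicolor	Panicoideae (PACMAD)	LEGDLYLKQRLRLRDAY	C3
3	Sorghum bicolor	Panicoideae (PACMAD)	LEGDPYLKQRLRIRDSY	C3
3	Sorghum bicolor	Panicoideae (PACMAD)	LEGDPYLKQRLRLRESY	C3
3	Sorghum bicolor	Panicoideae (PACMAD)	LEGDPYLKQRLRLRDAY	C3
3	Amaranthus hypochondriacus	Dicot	LDADPYLKQILRLRDPY	C4
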