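mouse	cohort	position	mutation	gene	annotation	frequency
A4	old	1219708	+1 T	ymgF→/ymgD←	Intergenic	0.94
A4	old	3293090	C → T	lpoA	R → C	0.23
A4	old	4540742	Δ 1 bp	fimE→/fimA→	Intergenic	0.77
A4	old	4540714-4541009	Inversion 296 bp	fimE→/fimA→	Intergenic	0.17
A4	old	4638770	IS5	yjjY→/yjtD→	Intergenic	0.11
A5	old	1219708	+1 T	ymgF→/ymgD←	Intergenic	0.85
A5	old	2404622	+6 TCGAGG	lrhA	Codon insertion	0.36
A5	old	3265168	IS5	tdcA←/tdcR→	Intergenic	0.16
A5	old	4540714-4541009	Inversion 296 bp	fimE→/fimA→	Intergenic	0.28
B6	old	1072335	G → T	rutA	Synonymous	0.05
B6	old	1219708	+1 T	ymgF→/ymgD←	Intergenic	0.22
B6	old	1269768	G → T	ldrC←/chaA←	Intergenic	0.06
B6	old	2257444	A → C	psuK←/fruA←	Intergenic	0.22
B6	old	2827271	A → T	srlR	D → V	0.08
B6	old	2827492	G → A	srlR	G → S	0.14
B6	old	3265168	IS5	tdcA←/tdcR→	Intergenic	0.06
B6	old	3502132	T → A	frlR	L → Q	0.13
B6	old	3741217	A → C	yiaK	Synonymous	0.05
B6	old	4409190	G → A	yjfJ	Synonymous	0.08
B7	old	1219708	+1 T	ymgF→/ymgD←	Intergenic	0.20
B7	old	1269768	G → T	ldrC←/chaA←	Intergenic	0.05
B7	old	2257444	A → C	psuK←/fruA←	Intergenic	0.62
B7	old	2447106	Δ 10 bp	smrB	Frameshift	0.05
B7	old	3265132	A → C	tdcA←/tdcR→	Intergenic	0.43
B7	old	3265168	IS5	tdcA←/tdcR→	Intergenic	0.65
B7	old	3375262	T → G	sspA	T → A	0.11
B10	old	1219708	+1 T	ymgF→/ymgD←	Intergenic	0.09
B10	old	1770086	IS5	ydiM	Gene interrupted	0.10
B10	old	2257444	A → C	psuK←/fruA←	Intergenic	0.88
B10	old	3057781	C → T	argP	R → C	0.09
B10	old	3265168	IS5	tdcA←/tdcR→	Intergenic	0.19
C13	old	1269768	G → T	ldrC←/chaA←	Intergenic	0.07
C13	old	1770086	IS5	ydiM	Gene interrupted	0.10
C13	old	1776568	C → T	ydiP	W → L	0.10
C13	old	2257444	A → C	psuK←/fruA←	Intergenic	1.00
C13	old	1127918-1174087	Nef		Prophage	0.50
C13	old	2497344-2544177	KingRac		Prophage	0.50
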