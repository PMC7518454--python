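mouse	cohort	position	mutation	gene	annotation	frequency
A2	young	70512	+1 A	araC	Frameshift	0.07
A2	young	2827142	T → C	srlR	L → S	0.05
A2	young	4540742	Δ 1 bp	fimE→/fimA→	Intergenic	0.83
B2	young	939933	Δ 220 bp	serS	Partial gene deletion	0.05
B2	young	1168829	IS2	ycfS	Gene interrupted	0.05
B2	young	2827246	A → T	srlR	K → *	0.07
B2	young	3098844	Δ 9 bp	ansB←/yggN←	Intergenic	0.05
B2	young	3174841	Δ 12 bp	cpdA	Codons deleted	0.05
B2	young	3375452	C → T	sspA←/rpsl←	Intergenic	0.87
B2	young	3471634	A → C	rpsG	L → S	0.07
B2	young	4359283	IS2	cadC	Gene interrupted	0.05
B2	young	4540742	Δ 1 bp	fimE→/fimA→	Intergenic	0.96
B2	young	4638629	IS2	yjjY←/yjtD→	Intergenic	0.05
D2	young	2257444	A → C	psuK←/fruA←	Intergenic	0.50
D2	young	3873062	G → A	dgoR	S → *	0.03
E2	young	1225143	G → C	minC	Synonymous	0.06
E2	young	2257444	A → C	psuK←/fruA←	Intergenic	0.53
E2	young	2435373	G → T	pdxB	Synonymous	0.08
E2	young	2827697	Δ 1 bp	srlR	Frameshift	0.12
E2	young	3383867	Δ 1 bp	yhcN→/yhcO←	Intergenic	0.06
E2	young	3502208	T → A	frlR	Y → *	0.20
G2	young	3497820	Δ 1 bp	yhfL→/frlA→	Intergenic	0.07
G2	young	3497842	G → T	yhfL→/frlA→	Intergenic	0.17
G2	young	3502108	T → C	frlR	L → P	0.43
G2	young	3502410	Δ 1 bp	frlR	Frameshift	0.15
G2	young	3502675	G → T	frlR	C → F	0.04
G2	young	3862987	A → T	yidE	Synonymous	0.06
G2	young	1127918-1174087	Nef		Prophage	0.10
G2	young	2497344-2544177	KingRac		Prophage	0.00
G2	young		Nef + KingRac		Prophage	0.90
H2	young	1054715	T → G	torS	Synonymous	0.05
H2	young	2257444	A → C	psuK←/fruA←	Intergenic	1.00
H2	young		Nef + KingRac		Prophage
I2	young	2257444	A → C	psuK←/fruA←	Intergenic	0.34
I2	young	3502108	T → C	frlR	L → P	0.10
I2	young	3502410	Δ 1 bp	frlR	Frameshift	0.10
I2	young	3502753	T → A	frlR	L → H	0.09
I2	young	3502339	Δ 1 bp	frlR	Frameshift	0.09
I2	young	3502519	T → G	frlR	I → S	0.06
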