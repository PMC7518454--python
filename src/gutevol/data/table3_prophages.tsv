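name	start	end	length_kb	completeness	keywords
Nef	1314728	1394436	79.7	Intact	Integrase, lysis, lysin, terminase, head, portal, capsid, tail
phage2	1809906	1835390	25.4	Incomplete	Terminase, integrase
phage3	2005260	2015055	9.7	Incomplete	Transposase
phage4	2086138	2130245	44.1	Intact	Transposase, lysin, terminase, portal, head, capsid, tail
phage5	2182740	2223082	40.3	Intact	Tail, plate, lysin, head, terminase, capsid, portal, recombinase, integrase
phage6	2286353	2333386	47.0	Intact	Integrase, lysin, lysis, terminase, portal, head, tail, plate
phage7	2611252	2651174	39.9	Intact	Lysin, tail, terminase, portal, protease, transposase
KingRac	2849919	2909216	59.2	Intact	Tail, head, portal, terminase, lysis, lysin, integrase
phage9	3492665	3543269	50.6	Intact	Tail, plate, capsid, head, portal, transposase, terminase, lysin, recombinase, integrase
phage10	4655459	4674687	19.2	Incomplete	Integrase, head, transposase
phage11	5206358	5241330	34.9	Questionable	Tail
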