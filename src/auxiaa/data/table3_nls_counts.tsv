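species	bp1_intact	bp1_degenerated	bp1_lack	bp2_intact	bp2_degenerated	bp2_lack	sv40_intact	sv40_degenerated	sv40_lack
Ricinus communis	13	0	8	12	8	1	17	4	0
Populus trichocarpa	22	0	14	22	10	4	29	6	1
Glycine max	41	1	21	39	16	8	51	8	4
Prunus persica	13	3	8	14	7	3	20	4	0
Gossypium raimondii	24	1	18	23	17	4	35	7	2
Arabidopsis thaliana	16	1	12	12	12	5	21	8	0
Utricularia gibba	15	0	10	13	12	0	19	3	3
Solanum tuberosum	16	0	9	15	6	4	19	4	2
Brachypodium distachyon	12	0	15	14	11	2	20	6	1
Oryza sativa	15	1	15	16	11	4	22	8	1
Zea mays	19	0	15	15	17	2	24	7	3
Phalaenopsis equestris	5	3	8	6	6	4	11	1	4
Amborella trichopoda	4	1	11	5	3	8	8	5	3
Picea abies	9	6	16	8	9	14	10	15	6
Selaginella moellendorffii	0	0	8	0	4	4	4	4	0
Physcomitrella patens	2	0	1	0	2	1	2	1	0
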