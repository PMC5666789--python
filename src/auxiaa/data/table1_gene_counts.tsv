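species	lineage	predicted_loci	aux_iaa_count
Chlamydomonas reinhardtii	Algae	17741	0
Physcomitrella patens	Moss	32926	3
Selaginella moellendorffii	Lycophytes	22285	9
Picea abies	Gymnosperm	58587	31
Amborella trichopoda	Amborellales	26846	16
Utricularia gibba	Dicots	28494	25
Solanum tuberosum	Dicots	35119	26
Gossypium raimondii	Dicots	37505	44
Arabidopsis thaliana	Dicots	27416	29
Populus trichocarpa	Dicots	41335	36
Ricinus communis	Dicots	31221	21
Prunus persica	Dicots	26873	24
Glycine max	Dicots	56044	63
Phalaenopsis equestris	Monocots	31384	16
Brachypodium distachyon	Monocots	34310	27
Oryza sativa	Monocots	42189	31
Zea mays	Monocots	63480	34
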