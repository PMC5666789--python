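species	pair	ka	ks	ka_ks	duplication_type
Physcomitrella patens	Phpat.008G051100/Phpat.024G023400	0.2242	1.0715	0.2092	segmental
Selaginella moellendorffii	15405070/15422644	0.0372	0.0869	0.4281	segmental
Picea abies	MA_10430843g0010/MA_10430843g0020	4.3721	2.6149	1.6720	tandem
Amborella trichopoda	AmTr_00002.512/AmTr_00002.514	0.3430	3.2896	0.1043	tandem
Amborella trichopoda	AmTr_00061.52/AmTr_00061.54	0.2000	3.5848	0.0558	tandem
Amborella trichopoda	AmTr_00061.52/AmTr_00061.55	0.3665	3.4483	0.1063	tandem
Amborella trichopoda	AmTr_00061.52/AmTr_00061.57	0.0721	0.1040	0.6933	tandem
Amborella trichopoda	AmTr_00061.54/AmTr_00061.55	0.3713	1.5216	0.2440	tandem
Amborella trichopoda	AmTr_00061.54/AmTr_00061.57	0.0429	0.0697	0.6163	tandem
Amborella trichopoda	AmTr_00061.55/AmTr_00061.57	0.3890	2.6067	0.1492	tandem
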