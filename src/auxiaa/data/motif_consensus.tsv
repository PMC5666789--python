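motif_id	pattern
m1	GDVPW
m2	VKVxM
m3	VGWPPV
m4	KRxRxxK
m5	LxLxLx
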