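compounds	R1	R2	R3	R4
1a,2a,3a	H	H	H	H
1b,2b,3b	Br	H	H	H
2b(M)	H	Br	H	H
1c,2c,3c	H	H	H	Br
2c(M)	H	H	Br	H
1d,2d,3d	Br	H	Br	H
2d(M)	H	Br	H	Br
1e,2e,3e	Br	Br	H	H
1f,2f,3f	Br	H	H	Br
2f(M)	H	Br	Br	H
1g,2g,3g	H	H	Br	Br
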