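compound	O1_H1_percent	O2_H2_percent
3a	66.9	67.7
3b	79.3	77.5
3c	2.6	2.7
3d	44.3	47.7
3e	96.8	96.7
3f	53.2	51.7
3g	3.1	3.1
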