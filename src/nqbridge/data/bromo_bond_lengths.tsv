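bond	2b_xray_mol1	2b_xray_mol2	2b_dft	2bM_xray	2bM_dft
C1=O	1.224	1.231	1.222	1.240	1.228
C4=O	1.207	1.205	1.211	1.218	1.205
C8-O	1.348	1.357	1.330	1.346	1.331
C1-C2	1.487	1.483	1.495	1.471	1.476
C2-Br	1.869	1.887	1.880	–	–
C3-Br	–	–	–	1.876	1.878
C2-C3	1.334	1.318	1.330	1.341	1.331
C3-C4	1.474	1.478	1.481	1.492	1.500
C4-C10	1.492	1.491	1.489	1.488	1.493
C10-C5	1.379	1.398	1.377	1.386	1.378
C5-C6	1.400	1.384	1.396	1.397	1.396
C6-C7	1.388	1.368	1.375	1.383	1.376
C7-C8	1.382	1.379	1.400	1.402	1.400
C8-C9	1.411	1.404	1.406	1.405	1.404
C9-C10	1.417	1.408	1.407	1.411	1.406
C1-C9	1.451	1.454	1.464	1.462	1.461
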