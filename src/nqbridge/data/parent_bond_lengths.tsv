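bond	1a_xray	1a_dft	2a_xray	2a_dft	3a_xray	3a_dft
C1=O	1.222	1.211	1.257	1.228	1.247	1.231
C4=O	1.223	1.211	1.205	1.211	1.240	1.231
C8-O	–	–	1.329	1.332	1.508	1.331
C5-O	–	–	–	–	1.341	1.331
C1-C2	1.474	1.484	1.437	1.479	1.478	1.477
C2-C3	1.332	1.331	1.350	1.331	1.343	1.332
C3-C4	1.473	1.484	1.478	1.484	1.478	1.447
C4-C10	1.486	1.491	1.500	1.492	1.476	1.459
C10-C5	1.393	1.389	1.339	1.378	1.402	1.391
C5-C6	1.384	1.385	1.413	1.396	1.417	1.412
C6-C7	1.388	1.390	1.389	1.376	1.384	1.364
C7-C8	1.382	1.385	1.416	1.400	1.430	1.412
C8-C9	1.394	1.389	1.388	1.404	1.309	1.391
C9-C10	1.404	1.397	1.380	1.408	1.433	1.421
C1-C9	1.490	1.491	1.477	1.463	1.461	1.459
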