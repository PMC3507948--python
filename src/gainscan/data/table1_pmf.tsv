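# MALDI-TOF peptide mass fingerprint of the 537-residue lamprey RPE65 band,
# as printed: centroid mass, theoretical (MS-Digest) mass, their printed
# difference (Da), relative intensity, and the peptide range/modification.
# centroid_mass	theoretical_mass	difference	relative_intensity	start	end	modification
796.4328	796.4312	0.0016	5.31	360	366	none
877.4239	877.4203	0.0036	45.69	414	420	pyroGlu-Q
894.4414	894.4468	-0.0054	66.58	414	420	none
933.493	933.4941	-0.0011	18.19	264	271	none
1114.549	1114.567	-0.0182	4.93	24	33	none
1128.484	1128.518	-0.0336	3.45	1	10	acetyl-Nterm
1130.58	1130.562	0.0174	10.29	24	33	oxidation-M
1246.659	1246.661	-0.0025	15.72	34	44	none
1262.673	1262.656	0.0164	11.6	34	44	oxidation-M
1319.642	1319.645	-0.0025	2.54	223	234	none
1419.693	1419.622	0.0716	7.49	321	332	none
1678.865	1678.866	-0.0009	35.54	171	185	none
1715.835	1715.816	0.0187	12.66	368	381	none
1759.891	1759.892	-1E-04	4.76	306	320	none
1871.939	1871.917	0.0211	20.87	367	381	none
1929.955	1929.971	-0.0159	16.97	397	413	none
1956.944	1956.949	-0.0048	6.29	430	446	none
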