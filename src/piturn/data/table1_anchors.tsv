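# Residue-mapping anchors for six nuclear-receptor ligand-binding domains.
# Columns: taxon, generic alignment position (1-based), native author residue
# number, amino acid at that anchor, secondary-structure element.
# Within one (taxon, element) block native numbering is contiguous with the
# alignment numbering.
hRXRalpha	109	305	W	H4-H5
hRXRalpha	111	307	E	H5
hRXRalpha	202	348	R	H7
hRXRalpha	206	352	E	H7
hRXRalpha	207	353	L	H7
hRXRalpha	210	356	K	H7
hRXRalpha	214	360	M	H7
hRXRalpha	220	366	E	H8
hRXRalpha	262	379	D	loopH8-H9
hRXRalpha	263	380	S	loopH8-H9
hRXRalpha	309	414	R	H10
hRXRalpha	316	421	R	H10
hRXRalpha	321	426	R	H11
hRXRalpha	322	427	S	H11
hRXRalpha	326	431	K	H11
hHNF4alpha	109	224	A	H4-H5
hHNF4alpha	111	226	E	H5
hHNF4alpha	202	267	R	H7
hHNF4alpha	206	271	E	H7
hHNF4alpha	207	272	L	H7
hHNF4alpha	210	275	P	H7
hHNF4alpha	214	279	L	H7
hHNF4alpha	220	285	E	H8
hHNF4alpha	262	298	D	loopH8-H9
hHNF4alpha	263	299	A	loopH8-H9
hHNF4alpha	309	333	R	H10
hHNF4alpha	316	340	L	H10
hHNF4alpha	321	345	Q	H11
hHNF4alpha	322	346	S	H11
hHNF4alpha	326	350	Q	H11
hCOUPTFII	109	249	W	H4-H5
hCOUPTFII	111	251	E	H5
hCOUPTFII	202	293	R	H7
hCOUPTFII	206	297	E	H7
hCOUPTFII	207	298	Q	H7
hCOUPTFII	210	301	K	H7
hCOUPTFII	214	305	L	H7
hCOUPTFII	220	311	E	H8
hCOUPTFII	262	324	D	loopH8-H9
hCOUPTFII	263	325	A	loopH8-H9
hCOUPTFII	309	359	R	H10
hCOUPTFII	316	366	R	H10
hCOUPTFII	321	371	R	H11
hCOUPTFII	322	372	T	H11
hCOUPTFII	326	376	S	H11
hPNR	109	257	W	H4-H5
hPNR	111	259	E	H5
hPNR	202	301	R	H7
hPNR	206	305	E	H7
hPNR	207	306	T	H7
hPNR	210	309	R	H7
hPNR	214	313	L	H7
hPNR	220	319	E	H8
hPNR	262	332	E	loopH8-H9
hPNR	263	333	T	loopH8-H9
hPNR	309	367	R	H10
hPNR	316	374	L	H10
hPNR	321	379	R	H11
hPNR	322	380	F	H11
hPNR	326	384	E	H11
hRARalpha	109	265	C	H4-H5
hRARalpha	111	267	D	H5
hRARalpha	202	307	D	H7
hRARalpha	206	311	A	H7
hRARalpha	207	312	F	H7
hRARalpha	210	315	Q	H7
hRARalpha	214	319	L	H7
hRARalpha	220	325	E	H8
hRARalpha	262	338	D	loopH8-H9
hRARalpha	263	339	R	loopH8-H9
hRARalpha	309	373	M	H10
hRARalpha	316	380	K	H10
hRARalpha	321	385	R	H11
hRARalpha	322	386	S	H11
hRARalpha	326	390	K	H11
hTRalpha	109	309	C	H4-H5
hTRalpha	111	311	E	H5
hTRalpha	202	351	D	H7
hTRalpha	206	355	D	H7
hTRalpha	207	356	L	H7
hTRalpha	210	359	S	H7
hTRalpha	214	363	F	H7
hTRalpha	220	369	E	H8
hTRalpha	262	382	D	loopH8-H9
hTRalpha	263	383	R	loopH8-H9
hTRalpha	309	417	F	H10
hTRalpha	316	424	K	H10
hTRalpha	321	429	R	H11
hTRalpha	322	430	M	H11
hTRalpha	326	434	C	H11
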