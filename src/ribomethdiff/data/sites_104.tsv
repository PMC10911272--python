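# Human rRNA 2'-O-methylation site catalog (104 entries) on mature-rRNA
# 1-based coordinates (18S=1869 nt, 5.8S=157 nt, 28S=5070 nt).
# SYNTHETIC FIXTURE: only the sites named in the source study carry real
# identities (SSU: A99, G436, C797, G867, C1272; LSU: G1303, A2388, G2411,
# C3680, G3723, G4588; 5.8S: U14, G75) and only SNORD57, SNORD87 and
# SNORD88A/B/C are real guide assignments.  All other positions and all
# SNORD2xx guide names are schematic placeholders so the catalog reaches the
# catalogued total of 104 sites; they must not be treated as biological truth.
subunit	position	nucleotide	label	guides
18S	99	A	SSU-A99	SNORD57
18S	121	G	SSU-G121	SNORD234
18S	151	G	SSU-G151	
18S	219	G	SSU-G219	
18S	295	G	SSU-G295	SNORD229
18S	328	G	SSU-G328	
18S	436	G	SSU-G436	SNORD201
18S	491	G	SSU-G491	SNORD230
18S	524	U	SSU-U524	SNORD235
18S	673	U	SSU-U673	
18S	692	U	SSU-U692	SNORD228
18S	775	C	SSU-C775	SNORD224
18S	797	C	SSU-C797	SNORD202
18S	833	C	SSU-C833	SNORD238
18S	867	G	SSU-G867	SNORD203
18S	986	G	SSU-G986	
18S	1026	C	SSU-C1026	SNORD239
18S	1043	A	SSU-A1043	SNORD222
18S	1058	G	SSU-G1058	
18S	1088	G	SSU-G1088	
18S	1100	G	SSU-G1100	
18S	1129	G	SSU-G1129	
18S	1164	G	SSU-G1164	
18S	1172	G	SSU-G1172	SNORD233
18S	1242	U	SSU-U1242	SNORD232
18S	1264	U	SSU-U1264	SNORD223
18S	1272	C	SSU-C1272	SNORD204
18S	1284	G	SSU-G1284	SNORD236
18S	1359	G	SSU-G1359	SNORD237
18S	1388	G	SSU-G1388	SNORD220
18S	1425	G	SSU-G1425	SNORD231
18S	1453	C	SSU-C1453	
18S	1482	C	SSU-C1482	
18S	1498	G	SSU-G1498	
18S	1680	C	SSU-C1680	SNORD226
18S	1709	G	SSU-G1709	SNORD227
18S	1760	G	SSU-G1760	
18S	1767	C	SSU-C1767	SNORD240
18S	1777	A	SSU-A1777	SNORD225
18S	1791	G	SSU-G1791	
18S	1801	A	SSU-A1801	
18S	1815	G	SSU-G1815	SNORD221
5.8S	14	U	5.8S-U14	
5.8S	75	G	5.8S-G75	
28S	194	C	LSU-C194	SNORD263
28S	244	G	LSU-G244	SNORD264
28S	295	A	LSU-A295	
28S	371	C	LSU-C371	SNORD259
28S	493	A	LSU-A493	
28S	537	G	LSU-G537	SNORD267
28S	638	C	LSU-C638	
28S	664	A	LSU-A664	SNORD254
28S	692	G	LSU-G692	SNORD242
28S	746	G	LSU-G746	SNORD266
28S	775	U	LSU-U775	
28S	892	G	LSU-G892	SNORD244
28S	1011	U	LSU-U1011	SNORD265
28S	1103	G	LSU-G1103	SNORD252
28S	1125	C	LSU-C1125	
28S	1303	G	LSU-G1303	SNORD205
28S	1346	G	LSU-G1346	SNORD249
28S	1423	U	LSU-U1423	
28S	1543	A	LSU-A1543	SNORD251
28S	1551	A	LSU-A1551	
28S	1621	G	LSU-G1621	SNORD257
28S	1656	A	LSU-A1656	
28S	1692	G	LSU-G1692	
28S	1734	G	LSU-G1734	SNORD258
28S	1794	C	LSU-C1794	SNORD261
28S	1825	C	LSU-C1825	SNORD250
28S	2388	A	LSU-A2388	SNORD206
28S	2411	G	LSU-G2411	SNORD207
28S	2427	G	LSU-G2427	SNORD246
28S	2608	C	LSU-C2608	
28S	2629	A	LSU-A2629	
28S	2722	A	LSU-A2722	SNORD255
28S	2742	G	LSU-G2742	
28S	2781	G	LSU-G2781	
28S	2829	G	LSU-G2829	
28S	2930	C	LSU-C2930	
28S	3062	G	LSU-G3062	SNORD247
28S	3243	C	LSU-C3243	
28S	3253	C	LSU-C3253	
28S	3362	U	LSU-U3362	
28S	3504	G	LSU-G3504	
28S	3558	G	LSU-G3558	
28S	3680	C	LSU-C3680	SNORD88A/B/C
28S	3708	G	LSU-G3708	SNORD256
28S	3723	G	LSU-G3723	SNORD87
28S	3907	A	LSU-A3907	SNORD243
28S	3989	G	LSU-G3989	SNORD248
28S	3997	C	LSU-C3997	
28S	4097	C	LSU-C4097	
28S	4134	C	LSU-C4134	
28S	4153	A	LSU-A4153	
28S	4282	G	LSU-G4282	
28S	4357	U	LSU-U4357	SNORD245
28S	4439	G	LSU-G4439	SNORD241
28S	4462	G	LSU-G4462	SNORD260
28S	4554	G	LSU-G4554	
28S	4588	G	LSU-G4588	SNORD208
28S	4673	C	LSU-C4673	SNORD253
28S	4744	A	LSU-A4744	SNORD262
28S	4756	G	LSU-G4756	
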