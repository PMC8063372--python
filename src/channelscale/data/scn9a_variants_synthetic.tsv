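# Synthetic SCN9A missense variant table.
#
# The pain-related and neutral variants that the source literature names in
# running text are listed first in each block; the remaining rows are
# SYNTHETIC filler (residues drawn inside the structural model's domain
# ranges DI 229-417, DII 839-972, DIII 1296-1461, DIV 1617-1763) so that the
# two label sets have the literature's sizes: 36 pain-related, 48 neutral.
residue_number	wt_aa	mut_aa	label
211	S	P	pain
823	L	R	pain
1538	W	R	pain
720	I	K	pain
739	I	V	pain
1596	T	I	pain
185	R	H	pain
136	I	V	pain
1461	I	T	pain
228	I	M	pain
400	V	M	pain
241	S	T	pain
1329	T	E	pain
1761	Y	I	pain
1717	D	V	pain
1298	L	A	pain
1356	Y	I	pain
1618	E	I	pain
1443	Q	M	pain
898	I	R	pain
1731	A	E	pain
302	R	F	pain
1343	R	Q	pain
1330	Q	P	pain
1421	V	W	pain
238	T	V	pain
373	G	C	pain
407	N	L	pain
951	L	V	pain
303	D	S	pain
960	I	T	pain
1697	R	W	pain
972	H	M	pain
1308	F	P	pain
1630	E	K	pain
1677	H	V	pain
1428	V	I	neutral
920	T	N	neutral
194	V	I	neutral
1613	V	I	neutral
1398	T	N	neutral
1399	I	D	neutral
1419	S	N	neutral
1662	D	A	neutral
1674	D	A	neutral
1700	K	A	neutral
145	M	L	neutral
146	M	S	neutral
1207	R	K	neutral
1210	T	N	neutral
890	D	N	neutral
1412	K	I	neutral
1415	K	I	neutral
946	Y	T	neutral
334	H	E	neutral
1386	C	F	neutral
1653	Y	M	neutral
395	G	I	neutral
897	Q	A	neutral
901	G	D	neutral
1638	E	N	neutral
381	Q	N	neutral
1366	F	S	neutral
253	M	Q	neutral
380	E	R	neutral
1706	V	D	neutral
1737	A	L	neutral
1337	A	Y	neutral
1309	Y	G	neutral
1393	Q	M	neutral
1629	V	W	neutral
874	E	T	neutral
1635	H	R	neutral
1636	S	D	neutral
1328	P	T	neutral
309	P	V	neutral
1626	S	L	neutral
848	K	N	neutral
310	V	G	neutral
964	M	T	neutral
312	D	R	neutral
967	H	F	neutral
1439	C	H	neutral
1736	E	M	neutral
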