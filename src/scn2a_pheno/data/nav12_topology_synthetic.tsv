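# Synthetic, approximate Na_V_1.2 (SCN2A) topology for testing and examples.
# Best-effort reconstruction of the canonical four-domain sodium-channel
# architecture (DI-DIV, segments S1-S6, S5-S6 pore loops, cytoplasmic linkers
# and termini) in UniProt-style 1-based inclusive intervals over a 2005-residue
# protein.  Interval boundaries are NOT the curated UniProt values: they were
# chosen to be structurally plausible and consistent with the published
# location labels of well-known recurrent variants (e.g. R853 in repeat II,
# L1342 in repeat III, R1882 cytoplasmic, R937 pore-forming).  Analyses that
# are sensitive to exact boundary placement should substitute a curated table.
domain	region	segment	start	end
-	Cytoplasmic	-	1	126
I	Transmembrane	S1	127	150
I	Extracellular	-	151	159
I	Transmembrane	S2	160	183
I	Cytoplasmic	-	184	192
I	Transmembrane	S3	193	216
I	Extracellular	-	217	225
I	Transmembrane	S4	226	248
I	Cytoplasmic	-	249	255
I	Transmembrane	S5	256	278
I	Extracellular	-	279	300
I	Pore-forming	-	301	325
I	Extracellular	-	326	335
I	Transmembrane	S6	336	360
-	Cytoplasmic	-	361	755
II	Transmembrane	S1	756	779
II	Extracellular	-	780	787
II	Transmembrane	S2	788	811
II	Cytoplasmic	-	812	819
II	Transmembrane	S3	820	843
II	Extracellular	-	844	851
II	Transmembrane	S4	852	875
II	Cytoplasmic	-	876	882
II	Transmembrane	S5	883	905
II	Extracellular	-	906	925
II	Pore-forming	-	926	950
II	Extracellular	-	951	960
II	Transmembrane	S6	961	985
-	Cytoplasmic	-	986	1203
III	Transmembrane	S1	1204	1227
III	Extracellular	-	1228	1235
III	Transmembrane	S2	1236	1259
III	Cytoplasmic	-	1260	1267
III	Transmembrane	S3	1268	1291
III	Extracellular	-	1292	1299
III	Transmembrane	S4	1300	1320
III	Cytoplasmic	-	1321	1340
III	Transmembrane	S5	1341	1365
III	Extracellular	-	1366	1420
III	Pore-forming	-	1421	1430
III	Extracellular	-	1431	1450
III	Transmembrane	S6	1451	1475
-	Cytoplasmic	-	1476	1530
IV	Transmembrane	S1	1531	1554
IV	Extracellular	-	1555	1562
IV	Transmembrane	S2	1563	1586
IV	Cytoplasmic	-	1587	1594
IV	Transmembrane	S3	1595	1618
IV	Extracellular	-	1619	1625
IV	Transmembrane	S4	1626	1644
IV	Cytoplasmic	-	1645	1655
IV	Transmembrane	S5	1656	1678
IV	Extracellular	-	1679	1720
IV	Pore-forming	-	1721	1735
IV	Extracellular	-	1736	1750
IV	Transmembrane	S6	1751	1780
-	Cytoplasmic	-	1781	2005
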