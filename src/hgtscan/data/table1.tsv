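gene	species	identity	donor_lineage	bp	au	length	frame	rpkm	editing_sites	compartment
atp1	R. cantleyi	HGT	Vitaceae	54	NS	1520	I	2370	1039	mitochondrial
atp1	R. tuan-mudae	HGT	Vitaceae	54	NS	1520	I			mitochondrial
atp1	S. himalayana	HGT	Vitaceae	54	NS	1514	I			mitochondrial
atp4	R. cantleyi	HGT	Cucurbitaceae	83	NS	526	I	6560	168, 337	mitochondrial
atp4	R. tuan-mudae	HGT	Cucurbitaceae	83	NS	526	I			mitochondrial
atp4	S. himalayana	HGT	Cucurbitaceae	83	NS	520	I			mitochondrial
atp9	R. cantleyi	VGT		94		204	I	1225		mitochondrial
atp9	R. tuan-mudae	VGT		94		204	I			mitochondrial
atp9	S. himalayana	VGT		94		204	I			mitochondrial
atp9	S. himalayana	HGT	Vitaceae	65	NS	195	I			mitochondrial
cob	R. cantleyi	VGT		96		1166	I	941		mitochondrial
cob	R. tuan-mudae	VGT		96		1166	I			mitochondrial
cob	S. himalayana	VGT		96		1166	I			mitochondrial
cob	S. himalayana	HGT	Vitaceae	99	0.0004	1179	I			mitochondrial
cox1	R. cantleyi	HGT	Brassicaceae+Caryophyllales	71	0.0360	1542	I	449		mitochondrial
cox1	R. tuan-mudae	HGT	Brassicaceae+Caryophyllales	71	0.0360	1542	I			mitochondrial
cox1	S. himalayana	HGT	Brassicaceae+Caryophyllales	71	0.0360	1542	I			mitochondrial
cox1	S. himalayana	HGT	Tetrastigma	100	<0.0001	1461	I			mitochondrial
cox2	R. cantleyi	-		<50		770	I	2183	14, 61, 153, 233	mitochondrial
cox2	R. tuan-mudae	-		<50		770	I			mitochondrial
cox2	S. himalayana	-		<50		771	I			mitochondrial
cox2	S. himalayana	HGT	Tetrastigma	96	<0.0001	246	I			mitochondrial
cox3	R. cantleyi	VGT		78		798	I	1810		mitochondrial
cox3	S. himalayana	VGT		78		798	I			mitochondrial
cox3	S. himalayana	HGT	Tetrastigma	85	0.0063	337	I			mitochondrial
rpl2	R. cantleyi	HGT	Vitaceae	51	NS	408	I	44		mitochondrial
rpl2	R. tuan-mudae	HGT	Vitaceae	51	NS	408	I			mitochondrial
rpl2	S. himalayana	HGT	Tetrastigma	69	NS	963	ψ			mitochondrial
rpl5	R. cantleyi	VGT		89		375	I	1619		mitochondrial
rpl5	R. tuan-mudae	VGT		89		375	I			mitochondrial
rpl5	S. himalayana	VGT		89		528	I			mitochondrial
rpl5	S. himalayana	HGT	Tetrastigma	100	0.0030	543	I			mitochondrial
rps1	R. cantleyi	HGT	Tetrastigma	100	<0.0001	342	I	155		mitochondrial
rps1	R. tuan-mudae	HGT	Tetrastigma	100	<0.0001	342	I			mitochondrial
rps1	S. himalayana	HGT	Tetrastigma	100	<0.0001	494	I			mitochondrial
rps4	R. cantleyi	VGT		96		838	I	2358	50, 61	mitochondrial
rps4	R. tuan-mudae	VGT		96		838	I			mitochondrial
rps4	S. himalayana	VGT		96		1040	I			mitochondrial
rps4	R. cantleyi	HGT	Tetrastigma	81	0.0075	143	I	99		mitochondrial
rps4	R. tuan-mudae	HGT	Tetrastigma	81	0.0075	143	I			mitochondrial
rps7	R. cantleyi	HGT	Vitaceae	96	0.0060	328	ψ	850		mitochondrial
rps7	R. tuan-mudae	HGT	Vitaceae	96	0.0060	328	ψ			mitochondrial
rps7	S. himalayana	HGT	Vitaceae	96	0.0060	186	ψ			mitochondrial
rps13	S. himalayana	HGT	Vitaceae	86	0.0033	264	ψ			mitochondrial
rps14	S. himalayana	HGT	Tetrastigma	68	0.0104	303	I			mitochondrial
sdh3	S. himalayana	HGT	Vitaceae	96	0.0102	272	I			mitochondrial
sdh4	R. cantleyi	-		<50		390	I	2902		mitochondrial
sdh4	S. himalayana	-		<50		390	I			mitochondrial
sdh4	S. himalayana	HGT	Vitaceae	63	NS	243	I			mitochondrial
atpA	R. tuan-mudae	HGT	Daucus	94	0.0044	515	ψ			plastid_origin
atpA	S. himalayana	HGT	Daucus	94	0.0044	457	ψ			plastid_origin
atpB	S. himalayana	HGT	Tetrastigma	100	0.0001	477	ψ			plastid_origin
atpI	S. himalayana	HGT	Tetrastigma	94	0.0003	100	I			plastid_origin
ndhB	S. himalayana	HGT	Tetrastigma	86	0.0133	447	I			plastid_origin
psaB	S. himalayana	HGT	Tetrastigma	92	0.0111	362	ψ			plastid_origin
psbA	S. himalayana	HGT	Tetrastigma	100	0.0001	395	ψ			plastid_origin
psbC	S. himalayana	HGT	Vitaceae	100	0.0004	969	ψ			plastid_origin
psbD	S. himalayana	HGT	Tetrastigma	100	<0.0001	753	ψ			plastid_origin
rbcL	S. himalayana	HGT	Vitaceae	82	NS	436	ψ			plastid_origin
rpoC1	S. himalayana	HGT	Tetrastigma	100	<0.0001	1613	ψ			plastid_origin
rpoC2	S. himalayana	HGT	Tetrastigma	100	0.0003	2000	ψ			plastid_origin
rps12	S. himalayana	HGT	Vitaceae	75	0.0304	222	ψ			plastid_origin
rrn16	S. himalayana	HGT	Tetrastigma	87	0.0297	1080	-			plastid_origin
rrn23	S. himalayana	HGT	Tetrastigma	99	0.0002	1638	-			plastid_origin
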