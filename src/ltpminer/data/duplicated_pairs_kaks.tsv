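species	gene1	gene2	subfamily	ka	ks	ratio	purifying	mode	age_mya
Ga	GaLTP12	GaLTP45	II	2.51E-07	5.85E-07	0.42952	yes	segmental	0.00011255
Ga	GaLTP18	GaLTP20	V	0.00737363	0.165432	0.0445719	yes	tandem	31.8138462
Ga	GaLTP37	GaLTP38	I	0.0728347	0.160261	0.454475	yes	tandem	30.8194231
Ga	GaLTP39	GaLTP42	II	0.0312662	0.0690421	0.452857	yes	tandem	13.2773269
Ga	GaLTP40	GaLTP41	II	0.0261638	0.111607	0.234428	yes	tandem	21.4628846
Ga	GaLTP47	GaLTP51	V	0.995287	1.01263	0.982869	yes	segmental	194.736538
Ga	GaLTP49	GaLTP50	I	0.0358127	0.0426301	0.84008	yes	tandem	8.19809615
Gr	GrLTP13	GrLTP14	II	0.0254554	0.128337	0.198347	yes	tandem	24.6801923
Gr	GrLTP21	GrLTP22	V	0.0185999	0.164891	0.112801	yes	tandem	31.7098077
Gr	GrLTP26	GrLTP27	I	2.48E-07	6.24E-07	0.397702	yes	tandem	0.00011993
Gr	GrLTP40	GrLTP41	I	0.0493708	0.0199624	2.47319	no	tandem	3.83892308
Gr	GrLTP45	GrLTP46	II	0.00500846	0.000100169	50	no	tandem	0.01926327
Gh	GhLTP10	GhLTP86	V	0.0168826	0.0310859	0.543095	yes	segmental	5.97805769
Gh	GhLTP22	GhLTP23	II	0.0148626	0.0889965	0.167002	yes	tandem	17.1147115
Gh	GhLTP51	GhLTP52	II	0.0187175	0.0303504	0.616713	yes	tandem	5.83661538
Gh	GhLTP53	GhLTP74	II	0.0663427	0.0389369	1.70385	no	segmental	7.48786538
Gh	GhLTP76	GhLTP77	IV	0.066261	0.127397	0.520114	yes	tandem	24.4994231
Gh	GhLTP82	GhLTP83	VIII	0.0595669	0.102935	0.578685	yes	tandem	19.7951923
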