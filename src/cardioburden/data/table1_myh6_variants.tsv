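coordinate	ref	alt	domain	exon	variant_name	subject_id	pp2	sift	inherit	pop_freq
23874837	A	T	head	4	Y115N	R0016	0.999	0	de novo	novel
23872623	C	A	head	10	Q277H	R0735	0.132	0	Mat	0.03%
23870180	C	T	head	13	D383N	07_155	0.986	0	NonPat	novel
23870173	G	A	head	13	S385L	10_121	0.157	0.04	Mat	novel
23870021	T	C	head	13	M436V	10_121	0.996	0.12	NonMat	novel
23869999	C	G	head	13	R443P	07_067	1	0	Pat	novel
23868064	T	G	head	15	D588A	11_099	1	0.26	Mat	0.17%
23865538	G	A	neck	20	R795W	R0023	0.998	0	Mat	0.01%
23863413	CTT	-	tail	21	K850-	07_074	NA	NA	NA	novel
23862995	G	A	tail	22	A936V	R0121	0.796	0.1	Pat	0.02%
23862912	C	A	tail	22	A964S	10_249	0.997	0.07	NA	0.22%
23862912	C	A	tail	22	A964S	09_299	0.997	0.07	NA	0.22%
23859545	C	T	tail	26	R1151Q	07_082	0.937	0.04	NA	novel
23858686	G	A	tail	28	A1298V	09_103	0.65	0.11	NA	0.01%
23858106	G	A	tail	29	T1379M	09_152	0.995	0.06	NA	0.06%
23858106	G	A	tail	29	T1379M	12_093	0.992	0.06	NA	0.06%
23857394	G	T	tail	30	A1443D	11_003	0.885	0.03	NA	novel
23856983	T	A	tail	31	E1503V	12_234	1	0.03	Mat	novel
23855732	C	T	tail	33	E1584K	09_204	0.889	0	Mat	novel
23854153	C	A	tail	35	E1754X	07_026	NA	NA	NA	0.01%
23853696	T	C	tail	36	K1840R	R0300	0.999	0.11	NA	0.02%
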