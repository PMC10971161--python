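sample_id	gene	variant_key	hgvs_c	zygosity	var_type	status_tNGS	status_WES	status_WGS	fn_cause_tNGS	fn_cause_WES	fn_cause_WGS
1	SLC2A2	3:170716187:T:C	c.1771-2A>G	hom	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
2	GCDH	19:13002736:del	c.219del	het	indel	LP_surfaced	VUS_surfaced	VUS_surfaced	.	.	.
2	GCDH	19:13004444:G:A	c.482G>A	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
3	CBS	21:44478972:C:T	c.1330G>A	het	SNV	LP_surfaced	LP_surfaced	not_surfaced	.	.	Low coverage and pseudogene
3	CBS	21:44484032:del3	c.805_807del	het	indel	LP_surfaced	LP_surfaced	not_surfaced	.	.	Low coverage and pseudogene
4	PCCB	3:136035806:dup	c.1050dup	het	indel	LP_surfaced	no_data	LP_surfaced	.	.	.
4	PCCB	3:136046016:delins	c.1278_1291delinsTAGAGCACAGGA	het	delins	LP_surfaced	no_data	LP_surfaced	.	.	.
5	PAH	12:103234177:C:T	c.1315+1G>A	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
5	PAH	12:103288604:G:T	c.261C>A	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
6	SLC22A5	5:131705516:G:A	c.-149G>A	het	SNV	LP_surfaced	not_surfaced	not_surfaced	.	3'UTR variant filtered out, but present in raw data/other variant VUS	3'UTR variant filtered out, but present in raw data/other variant VUS
6	SLC22A5	5:131719951:G:A	c.610G>A	het	SNV	VUS_surfaced	not_surfaced	not_surfaced	.	.	.
7	SLC2A1	1:43395707:C:G	c.517-1G>C	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
8	PCCA	13:100888120:G:C	c.625G>C	het	SNV	VUS_surfaced	VUS_surfaced	VUS_surfaced	.	.	.
8	PCCA	13:100925458:dup	c.923dup	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
9	OAT	10:126089510:C:T	c.1058G>A	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
9	OAT	10:126086661:del	c.1171del	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
10	ACADM	1:76198409:T:C	c.199T>C	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
10	ACADM	1:76226846:A:G	c.985A>G	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
11	SLC52A3	20:744576:G:C	c.639C>G	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
11	SLC52A3	20:744542:del3	c.678_680del	het	indel	VUS_surfaced	VUS_surfaced	VUS_surfaced	.	.	.
12	FAH	15:80464558:T:G	c.674T>G	het	SNV	VUS_surfaced	VUS_surfaced	VUS_surfaced	.	.	.
12	FAH	15:80472572:G:A	c.1062+5G>A	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
13	ASS1	9:133352345:del8	c.685_688+4del	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
13	ASS1	9:133355813:G:A	c.815G>A	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
14	BCKDHB	6:80982870:C:T	c.970C>T	hom	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
15	GAMT	19:1398988:A:G	c.497T>C	hom	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
16	ETFB	19:51848627:del3	c.614_616delAGA	hom	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
17	MMACHC	1:45973222:G:T	c.276G>T	hom	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
18	ACAT1	11:108010834:C:T	c.662C>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
18	ACAT1	11:108016927:A:C	c.1006-2A>C	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
19	MMUT	6:49425703:G:A	c.454C>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
19	MMUT	6:49425502:T:A	c.665A>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
20	OTC	X:38271205:C:T	c.958C>T	hom	SNV	LP_surfaced	LP_surfaced	no_data	.	.	.
21	ACADVL	17:7123482:del	c.104del	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
21	ACADVL	17:7125591:T:C	c.848T>C	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
22	SLC52A2	8:145583300:dup	c.148dup	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
22	SLC52A2	8:145584264:T:C	c.1016T>C	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
23	MMACHC	1:45973217:dup	c.271dup	het	indel	no_data	no_data	LP_surfaced	.	.	.
23	MMACHC	1:45973222:G:T	c.276G>T	het	SNV	no_data	no_data	LP_surfaced	.	.	.
24	DNAJC12	10:69583144:del	c.85del	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
24	DNAJC12	10:69556875:C:A	c.596G>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
25	ALDH7A1	5:1288206:del	c.1513del	hom	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
26	IVD	15:40699855:A:T	c.163A>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
26	IVD	15:40710350:A:G	c.1169A>G	het	SNV	VUS_surfaced	VUS_surfaced	VUS_surfaced	.	.	.
27	HMGCL	1:24147022:C:T	c.122G>A	hom	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
28	CTNS	17:3493545_3564028:del	57kb_deletion_incl_CTNS	het	CNV_del	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
28	CTNS	17:3543518:del4	c.18_21del	hemi	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
29	G6PC	17:41052972:del	c.79del	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
29	G6PC	17:41063157:del	c.788del	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
30	ETFA	15:76603769:C:T	c.-40G>A	hom	SNV	not_surfaced	not_surfaced	not_surfaced	hom. VUS/present in raw data	hom. VUS/present in raw data	hom. VUS/present in raw data
31	ABCD1	X:152991164:A:G	c.443A>G	hemi	SNV	LP_surfaced	LP_surfaced	not_surfaced	.	.	Low coverage and pseudogene
32	AGL	1:100316614:C:T	c.16C>T	het	SNV	no_data	LP_surfaced	LP_surfaced	.	.	.
32	AGL	1:100387137:dup	c.4529dup	het	indel	no_data	LP_surfaced	LP_surfaced	.	.	.
33	ASL	7:65551586:T:C	c.461T>C	het	SNV	LP_surfaced	no_data	LP_surfaced	.	.	.
33	ASL	7:65551738:G:A	c.532G>A	het	SNV	LP_surfaced	no_data	LP_surfaced	.	.	.
34	BCKDHA	19:41916527:T:A	c.109-15T>A	hom	SNV	not_surfaced	not_surfaced	not_surfaced	hom. VUS/present in raw data	hom. VUS/present in raw data	hom. VUS/present in raw data
35	BTD	3:15676984:delins	c.98_104delinsTCC	het	delins	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
36	CAD	2:27460617:C:T	c.4595C>T	hom	SNV	not_surfaced	not_surfaced	not_surfaced	hom. VUS/present in raw data	hom. VUS/present in raw data	hom. VUS/present in raw data
37	CPT2	1:53666438:C:G	c.200C>G	het	SNV	LP_surfaced	VUS_surfaced	VUS_surfaced	.	.	.
37	CPT2	1:53676026:C:T	c.680C>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
38	CYP27A1	2:219677818:C:T	c.1016C>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
38	CYP27A1	2:219678909:C:T	c.1183C>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
39	FOLR1	11:71906952:T:C	c.505T>C	hom	SNV	not_surfaced	LP_surfaced	LP_surfaced	hom. VUS/present in raw data	.	.
40	GYS2	12:1955262_22837888:del	deletion_incl_GYS2	het	CNV_del	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
40	GYS2	GYS2:c.495+1G>T	c.495+1G>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
41	HADHA	2:26418053:C:G	c.1528G>C	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
41	HADHA	2:26414401:del	c.2099del	het	indel	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
42	HMGCS2	1:120307008:G:A	c.346C>T	het	SNV	VUS_surfaced	not_surfaced	no_data	.	.	.
42	HMGCS2	1:120302538:C:T	c.634G>A	het	SNV	LP_surfaced	LP_surfaced	no_data	.	.	.
43	MCCC1	3:18278896:A:T	c.639+2T>A	hom	SNV	LP_surfaced	LP_surfaced	no_data	.	.	.
44	MCCC2	5:70945074:C:T	c.1367C>T	het	SNV	LP_surfaced	VUS_surfaced	VUS_surfaced	.	.	.
44	MCCC2	5:70948566:A:G	c.1559A>G	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
45	OXCT1	5:41803250:C:T	c.971G>A	hom	SNV	no_data	LP_surfaced	LP_surfaced	.	.	.
46	TH	11:2189135:C:T	c.698G>A	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
46	TH	11:2186980:G:A	c.1211C>T	het	SNV	VUS_surfaced	VUS_surfaced	VUS_surfaced	.	.	.
47	SLC2A1	1:43395453:T:A	c.680-2A>T	het	SNV	LP_surfaced	LP_surfaced	LP_surfaced	.	.	.
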