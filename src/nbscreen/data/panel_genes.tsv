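gene	moi	disorder	chrom	mild_phenotype
ABCD1	XLR	X-linked adrenoleukodystrophy	X	0
ACADM	AR	Medium-chain acyl-CoA dehydrogenase deficiency	1	0
ACADVL	AR	Very-long-chain acyl-CoA dehydrogenase deficiency	17	1
ACAT1	AR	Beta-ketothiolase deficiency	11	0
AGL	AR	Glycogen storage disease type III	1	0
ALDH7A1	AR	Pyridoxine-dependent epilepsy	5	0
ASL	AR	Argininosuccinic aciduria	7	0
ASS1	AR	Citrullinemia type I	9	0
BCKDHA	AR	Maple syrup urine disease type Ia	19	0
BCKDHB	AR	Maple syrup urine disease type Ib	6	0
BTD	AR	Biotinidase deficiency	3	0
CAD	AR	CAD deficiency (EIEE50)	2	0
CBS	AR	Classical homocystinuria	21	0
CPT1A	AR	Carnitine palmitoyltransferase I deficiency	11	1
CPT2	AR	Carnitine palmitoyltransferase II deficiency	1	0
CTNS	AR	Nephropathic cystinosis	17	0
CYP27A1	AR	Cerebrotendinous xanthomatosis	2	0
DNAJC12	AR	Hyperphenylalaninemia, DNAJC12 deficiency	10	0
ETFA	AR	Glutaric acidemia type IIA	15	0
ETFB	AR	Glutaric acidemia type IIB	19	0
FAH	AR	Tyrosinemia type I	15	0
FOLR1	AR	Cerebral folate transport deficiency	11	0
G6PC	AR	Glycogen storage disease type Ia	17	0
GAMT	AR	Guanidinoacetate methyltransferase deficiency	19	0
GCDH	AR	Glutaric acidemia type I	19	0
GYS2	AR	Glycogen storage disease type 0	12	0
HADHA	AR	LCHAD deficiency	2	0
HMGCL	AR	HMG-CoA lyase deficiency	1	0
HMGCS2	AR	HMG-CoA synthase-2 deficiency	1	0
IVD	AR	Isovaleric acidemia	15	0
MCCC1	AR	3-methylcrotonyl-CoA carboxylase 1 deficiency	3	1
MCCC2	AR	3-methylcrotonyl-CoA carboxylase 2 deficiency	5	1
MMACHC	AR	Methylmalonic aciduria with homocystinuria cblC	1	0
MMUT	AR	Methylmalonic acidemia mut type	6	0
OAT	AR	Gyrate atrophy	10	0
OTC	XLR	Ornithine transcarbamylase deficiency	X	0
OXCT1	AR	Succinyl-CoA:3-oxoacid CoA transferase deficiency	5	0
PAH	AR	Phenylketonuria	12	0
PCCA	AR	Propionic acidemia PCCA type	13	0
PCCB	AR	Propionic acidemia PCCB type	3	0
SI	AR	Congenital sucrase-isomaltase deficiency	3	0
SLC22A5	AR	Primary carnitine deficiency	5	0
SLC2A1	AD	GLUT1 deficiency syndrome	1	0
SLC2A2	AR	Fanconi-Bickel syndrome	3	0
SLC52A2	AR	Riboflavin transporter deficiency type 2	8	0
SLC52A3	AR	Riboflavin transporter deficiency type 3	20	0
TH	AR	Tyrosine hydroxylase-deficient dopa-responsive dystonia	11	0
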