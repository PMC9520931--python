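code	population	in_diaspora	super_population	ethnicity
CEU	Utah Residents (CEPH) with Northern/Western Eur. Ancestry	yes	EUR	White
TSI	Toscani in Italia	no	EUR	White
FIN	Finnish in Finland	no	EUR	White
GBR	British in England and Scotland	no	EUR	White
IBS	Iberian Population in Spain	no	EUR	White
YRI	Yoruba in Ibadan, Nigeria	no	AFR	Black or african american
LWK	Luhya in Webuye, Kenya	no	AFR	Black or african american
GWD	Gambian in Western Divisions in the Gambia	no	AFR	Black or african american
MSL	Mende in Sierra Leone	no	AFR	Black or african american
ESN	Esan in Nigeria	no	AFR	Black or african american
ASW	Americans of African Ancestry in SW USA	no	AFR	Black or african american
ACB	African Caribbeans in Barbados	no	AFR	Black or african american
MXL	Mexican Ancestry from Los Angeles USA	no	AMR	Latin american
PUR	Puerto Ricans from Puerto Rico	no	AMR	Latin american
CLM	Colombians from Medellin, Colombia	no	AMR	Latin american
PEL	Peruvians from Lima, Peru	no	AMR	Latin american
GIH	Gujarati Indian from Houston, Texas	yes	SAS	Asian
PJL	Punjabi from Lahore, Pakistan	no	SAS	Asian
BEB	Bengali from Bangladesh	no	SAS	Asian
STU	Sri Lankan Tamil from the UK	yes	SAS	Asian
ITU	Indian Telugu from the UK	yes	SAS	Asian
CHB	Han Chinese in Beijing, China	no	EAS	Asian
JPT	Japanese in Tokyo, Japan	no	EAS	Asian
CHS	Southern Han Chinese	no	EAS	Asian
CDX	Chinese Dai in Xishuangbanna, China	no	EAS	Asian
KHV	Kinh in Ho Chi Minh City, Vietnam	no	EAS	Asian
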