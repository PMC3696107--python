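Probeset ID	Gene Title	Gene Symbol	Chromosomal Location	p-value	FDR	FC
228904_at	homeobox B3	HOXB3	chr17q21.3	0,0018	0,0034	9,89
204424_s_at	LIM domain only 3 (rhombotin-like 2)	LMO3	chr12p12.3	0,0040	0,0044	8,35
205366_s_at	homeobox B6	HOXB6	chr17q21.3	0,0030	0,0042	6,23
235521_at	homeobox A3	HOXA3	chr7p15-p14	0,0029	0,0042	5,34
213931_at	inhibitor of DNA binding 2, dominant negative helix-loop-helix protein///inhib	ID2///ID2B	chr2p25///chr3p14.2	0,0008	0,0025	3,16
214457_at	homeobox A2	HOXA2	chr7p15-p14	0,0027	0,0042	2,45
239791_at	similar to hCG2042068	LOC100130740	chr17q21.32	0,0010	0,0025	2,31
1557051_s_at	–	–	–	0,0031	0,0042	2,22
208470_s_at	haptoglobin///haptoglobin-related protein	HP///HPR	chr16q22.1	0,0044	0,0046	2,22
232054_at	protocadherin 20	PCDH20	chr13q21	0,0034	0,0042	2,12
239966_at	–	–	–	0,0010	0,0025	2,07
217511_at	Kazal-type serine peptidase inhibitor domain 1	KAZALD1	chr10q24.31	0,0027	0,0042	2,05
242379_at	–	–	–	0,0041	0,0044	2,03
238768_at	chromosome 2 open reading frame 68	C2orf68	chr2p11.2	0,0017	0,0034	−2,01
205964_at	zinc finger protein 426	ZNF426	chr19p13.2	0,0003	0,0018	−2,01
205037_at	RAB, member of RAS oncogene family-like 4	RABL4	chr22q13.1	0,0009	0,0025	−2,03
235729_at	zinc finger protein 514	ZNF514	chr2q11.1	0,0004	0,0020	−2,03
204963_at	sarcospan (Kras oncogene-associated gene)	SSPN	chr12p11.2	0,0031	0,0042	−2,06
211651_s_at	laminin, beta 1	LAMB1	chr7q22	0,0011	0,0025	−2,08
225330_at	insulin-like growth factor 1 receptor	IGF1R	chr15q26.3	0,0011	0,0025	−2,09
226231_at	–	–	–	0,0010	0,0025	−2,09
233576_at	3-hydroxymethyl-3-methylglutaryl-Coenzyme A lyase-like 1	HMGCLL1	chr6p12.1	0,0009	0,0025	−2,12
229092_at	nuclear receptor subfamily 2, group F, member 2	NR2F2	chr15q26	0,0035	0,0042	−2,13
230561_s_at	chromosome 2 open reading frame 67	C2orf67	chr2q34	<0,0001	0,0016	−2,15
213424_at	KIAA0895 protein	KIAA0895	chr7p14.2	0,0011	0,0025	−2,20
223089_at	vezatin, adherens junctions transmembrane protein	VEZT	chr12q22	0,0010	0,0025	−2,22
214808_at	–	–	–	0,0003	0,0018	−2,23
228397_at	taurine upregulated gene 1	TUG1	chr22q12.2	0,0028	0,0042	−2,28
209120_at	nuclear receptor subfamily 2, group F, member 2	NR2F2	chr15q26	0,0033	0,0042	−2,36
225662_at	sterile alpha motif and leucine zipper containing kinase AZK	ZAK	chr2q24.2	0,0035	0,0042	−2,38
219381_at	chromosome 5 open reading frame 42	C5orf42	chr5p13.2	0,0003	0,0018	−2,38
204363_at	coagulation factor III (thromboplastin, tissue factor)	F3	chr1p22-p21	0,0048	0,0049	−2,38
220987_s_at	chromosome 11 open reading frame 17///NUAK family, SNF1-like kinase, 2	C11orf17///NUAK2	chr11p15.3///chr1q32.1	0,0035	0,0042	−2,43
209703_x_at	methyltransferase like 7A	METTL7A	chr12q13.13	0,0020	0,0036	−2,44
225946_at	Ras association (RalGDS/AF-6) domain family (N-terminal) member 8	RASSF8	chr12p12.3	0,0010	0,0025	−2,45
205020_s_at	ADP-ribosylation factor-like 4A	ARL4A	chr7p21-p15.3	0,0003	0,0018	−2,46
228106_at	chromosome 4 open reading frame 30	C4orf30	chr4p15.32	0,0030	0,0042	−2,46
214298_x_at	septin 6	SEP6	chrXq24	0,0050	0,0050	−2,49
215046_at	chromosome 2 open reading frame 67	C2orf67	chr2q34	0,0043	0,0046	−2,56
210869_s_at	melanoma cell adhesion molecule	MCAM	chr11q23.3	0,0034	0,0042	−2,63
218326_s_at	leucine-rich repeat-containing G protein-coupled receptor 4	LGR4	chr11p14-p13	0,0039	0,0044	−2,64
201505_at	laminin, beta 1	LAMB1	chr7q22	0,0002	0,0018	−2,65
209681_at	solute carrier family 19 (thiamine transporter), member 2	SLC19A2	chr1q23.3	0,0008	0,0025	−2,67
242691_at	–	–	–	0,0002	0,0018	−2,67
204004_at	PRKC, apoptosis, WT1, regulator	PAWR	chr12q21	0,0007	0,0025	−2,70
241879_at	–	–	–	0,0020	0,0036	−2,71
226374_at	–	–	–	0,0041	0,0044	−2,72
244043_at	–	–	–	0,0017	0,0034	−2,73
203627_at	insulin-like growth factor 1 receptor	IGF1R	chr15q26.3	<0,0001	0,0004	−2,78
227320_at	family with sequence similarity 101, member A	FAM101A	chr12q24.31	0,0030	0,0042	−2,80
200953_s_at	cyclin D2	CCND2	chr12p13	0,0040	0,0044	−2,80
227911_at	Rho GTPase activating protein 28	ARHGAP28	chr18p11.31	0,0033	0,0042	−2,88
1557293_at	hypothetical gene supported by AK128346	LOC440993	chr3q29	0,0010	0,0025	−2,92
203628_at	insulin-like growth factor 1 receptor	IGF1R	chr15q26.3	0,0003	0,0018	−3,02
212913_at	chromosome 6 open reading frame 26///mutS homolog 5 (E. coli)	C6orf26///MSH5	chr6p21.3///chr6p21.33	0,0030	0,0042	−3,81
226750_at	La ribonucleoprotein domain family, member 2	LARP2	chr4q28.2	0,0004	0,0022	−3,85
205848_at	growth arrest-specific 2	GAS2	chr11p14.3-p15.2	0,0017	0,0034	−4,19
202345_s_at	fatty acid binding protein 5 (psoriasis-associated)///fatty acid binding prote	FABP5///FABP5L2///FABP5L7	chr11q12.1///chr13q14.3///chr8q21.13	0,0011	0,0025	−6,37
230781_at	–	–	–	<0,0001	0,0018	−21,05
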