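gene	uniprot	protein_name	p_value	fold_change
PCYOX1	Q9UHG3	Prenylcysteine oxidase 1	4.84E-12	2.749
HBA1	P69905	Haemoglobin subunit alpha	5.43E-12	4.846
ECM1	Q16610	Extracellular matrix protein 1	5.45E-12	2.238
MBL2	P11226	Mannose-binding protein C	1.21E-10	6.665
RAB5C	P51148	Ras-related protein Rab-5C	4.33E-10	5.913
RHOF	Q9HBH0	Rho-related GTP-binding protein RhoF	5.38E-08	2.673
RNASE4	P34096	Ribonuclease 4	7.16E-08	3.486
RBP4	Q5VY30	Retinol-binding protein 4	1.07E-07	3.614
HSPE1	P61604	10 kDa heat shock protein, mitochondrial	7.50E-07	3.593
UBC	P0CG48	Polyubiquitin-C	7.93E-07	3.701
APOC4	P55056	Apolipoprotein C-IV	1.39E-06	2.617
MGP	P08493	Matrix Gla protein	5.45E-06	4.852
PRKCSH	K7ELL7	Glucosidase 2 subunit beta	2.64E-05	2.849
BTD	P43251	Biotinidase	6.20E-05	2.337
LCAT	P04180	Phosphatidylcholine-sterol acyltransferase	1.32E-04	2.146
CFHR5	Q9BXR6	Complement factor H-related protein 5	1.40E-04	2.099
DPY19L1	A0A1B0GW05	Probable C-mannosyltransferase DPY19L1	1.41E-04	2.165
GRB2	P62993	Growth factor receptor-bound protein 2	2.82E-04	3.229
STIM1	Q13586	Stromal interaction molecule 1	9.88E-04	2.452
ANG	P03950	Angiogenin	2.58E-03	2.327
PSMA7	O14818	Proteasome subunit alpha type-7	3.48E-03	2.146
TFPI	P10646	Tissue factor pathway inhibitor	3.75E-03	2.253
PRDX5	P30044	Peroxiredoxin-5, mitochondrial	3.80E-03	2.545
ZC3HAV1L	Q96H79	Zinc finger CCCH-type antiviral protein 1-like	4.43E-03	2.088
ABI1	A0A0A0MRT6	Abl interactor 1	7.33E-03	2.111
HBG1	A0A2R8Y7X9	Haemoglobin subunit gamma-1	9.76E-03	2.067
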