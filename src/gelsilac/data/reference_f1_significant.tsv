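accession	name	log2_lh	p_value	coverage
Q3TZN9	ABCC4/MRP4 efflux transporter	+	0.000	34.9
Q91YW3	DnaJ homolog subfamily C member 3 (p58IPK)	4.48	0.000	20.2
Q3TYT8	Collectin-12	3.34	0.000	6.1
P01899	H-2 class I histocompatibility antigen, D-B alpha chain precursor	3.06	0.000	12.4
Q3U651	Cathepsin D	2.44	0.000	5.1
P01900	H-2 class I histocompatibility antigen, D-D alpha chain precursor	2.16	0.000	37.5
Q91VK4	Integral membrane protein 2C (CT-BRI3)	2.00	0.000	20.4
P28798	Granulins precursor (proepithelin)	1.99	0.000	13.9
Q810U4	Neuronal cell adhesion molecule precursor (NrCam)	1.95	0.000	13.6
P10404	MLV-related proviral Env polyprotein precursor	1.90	0.000	6.2
Q61207	Sulfated glycoprotein 1 precursor (prosaposin)	1.81	0.001	11.3
P12023	Amyloid beta A4 protein precursor (APP)	1.75	0.001	12.3
P97333	Neuropilin-1 precursor (CD304)	1.64	0.002	22.0
O09126	Semaphorin-4D precursor (CD100)	1.63	0.002	8.7
Q80V26	Inositol monophosphatase 3	1.58	0.003	6.2
P06797	Cathepsin L1 precursor	1.56	0.004	34.4
Q61469	Lipid phosphate phosphohydrolase 1 (PAP-2a)	1.53	0.004	5.7
Q8K482	EMILIN-2 precursor	1.48	0.006	8.3
P03975	IgE-binding protein (IAP)	1.48	0.006	19.4
Q9D620	Rab11 family-interacting protein 1 (Rab-coupling protein)	1.33	0.013	7.6
P42082	T-lymphocyte activation antigen CD86	1.32	0.014	20.4
Q60751	Insulin-like growth factor 1 receptor precursor (CD221)	1.29	0.016	8.3
Q05910	ADAM 8 precursor (CD156a)	1.28	0.017	11.6
Q8BWW9	Serine/threonine-protein kinase N2	1.27	0.017	14.3
P01902	H-2 class I histocompatibility antigen, K-D alpha chain precursor	1.25	0.019	29.3
P27512	Tumor necrosis factor receptor superfamily member 5 precursor (CD40)	1.21	0.023	12.8
P10923	Osteopontin precursor	1.21	0.024	15.0
P16675	Lysosomal protective protein precursor (Cathepsin A)	1.20	0.025	14.1
A2AR26	Solute carrier family 2, member 6 (Slc2a6)	1.18	0.027	7.9
O89103	Complement component C1q receptor precursor	1.18	0.028	30.0
O89017	Legumain precursor	1.16	0.030	17.7
O35474	EGF-like repeat and discoidin I-like domain-containing protein 3 precursor	1.14	0.033	9.6
P35951	Low-density lipoprotein receptor precursor	1.12	0.036	12.0
P58681	Toll-like receptor 7 precursor	-4.41	0.000	11.0
P47738	Aldehyde dehydrogenase, mitochondrial precursor	-2.74	0.000	24.1
P53026	60S ribosomal protein L10a	-2.61	0.000	18.9
A1L314	Macrophage expressed gene 1 protein (Mpeg1)	-2.14	0.000	18.0
Q03265	ATP synthase subunit alpha, mitochondrial precursor	-2.07	0.000	28.2
Q61549	Cell surface glycoprotein F4/80	-1.78	0.001	6.8
P24063	Integrin alpha-L precursor (CD11a)	-1.72	0.002	21.8
Q3TVQ0	Formyltetrahydrofolate synthetase domain containing 1	-1.61	0.003	4.1
Q7TPV4	Myb-binding protein 1A	-1.54	0.004	11.0
Q8CGK3	Lon protease homolog, mitochondrial precursor	-1.54	0.004	4.0
P26443	Glutamate dehydrogenase 1, mitochondrial precursor	-1.42	0.009	9.5
Q3TFD0	Serine hydroxymethyltransferase	-1.42	0.009	22.8
P51675	C-C chemokine receptor type 1 (CD191)	-1.42	0.009	8.2
P63038	60 kDa heat shock protein, mitochondrial precursor	-1.37	0.012	36.8
Q99KI0	Aconitate hydratase, mitochondrial precursor	-1.37	0.012	11.2
P38647	Stress-70 protein, mitochondrial precursor	-1.37	0.012	8.0
Q6P5F7	Protein tweety homolog 3	-1.37	0.012	4.8
Q8CGC6	RNA-binding protein 28	-1.26	0.020	4.0
Q91VE6	MKI67 FHA domain-interacting nucleolar phosphoprotein	-1.16	0.033	13.2
P20152	Vimentin	-1.13	0.038	67.4
Q69ZN7	Myoferlin	-1.12	0.039	54.2
P21956	Lactadherin precursor	-1.11	0.040	21.8
P57746	Vacuolar ATP synthase subunit D	-1.11	0.040	18.6
Q60932	Voltage-dependent anion-selective channel protein 1	-1.09	0.045	39.9
Q3TJG0	Band 4.1-like protein 5	-1.07	0.049	8.1
P50516	Vacuolar ATP synthase catalytic subunit A	-1.07	0.049	42.5
Q9DBG7	Signal recognition particle receptor subunit alpha (SRPa)	-1.07	0.049	8.5
Q8JZR0	Long-chain-fatty-acid-CoA ligase 5	-1.07	0.049	4.1
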