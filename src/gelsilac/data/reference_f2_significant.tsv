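accession	name	log2_lh	p_value	coverage
Q3TZN9	ABCC4/MRP4 efflux transporter	+	0.000	26.9
Q91YW3	DnaJ homolog subfamily C member 3 (p58IPK)	3.83	0.000	20.0
P01899	H-2 class I histocompatibility antigen, D-B alpha chain precursor	2.32	0.000	12.4
Q810U4	Neuronal cell adhesion molecule precursor (NrCam)	2.28	0.000	7.1
A2AR26	Solute carrier family 2, member 6 (Slc2a6)	2.09	0.000	11.7
P63085	Mitogen-activated protein kinase 1 (p42-MAPK)	2.09	0.000	30.2
Q61213	Gag	2.02	0.000	4.6
P03975	IgE-binding protein (IAP)	1.99	0.000	36.6
P01900	H-2 class I histocompatibility antigen, D-D alpha chain precursor	1.80	0.000	23.3
Q3UT74	Integrin alpha 9 protein (Itga9)	1.67	0.000	8.4
P26955	Cytokine receptor common subunit beta (CD131)	1.48	0.001	8.4
P97333	Neuropilin-1 precursor	1.38	0.001	15.0
Q921H8	3-ketoacyl-CoA thiolase A, peroxisomal precursor	1.38	0.001	16.0
Q61207	Sulfated glycoprotein 1 precursor (prosaposin)	1.33	0.002	7.5
Q8C166	Copine-1	1.32	0.002	6.3
Q9JLZ8	Single Ig IL-1-related receptor	1.31	0.002	7.8
Q9D620	Rab11 family-interacting protein 1 (Rab-Coupling protein)	1.31	0.002	24.5
Q05910	ADAM 8 precursor (CD156a)	1.29	0.003	7.7
Q99LS5	Tex264 protein	1.28	0.003	4.5
P12265	Beta-glucuronidase precursor	1.22	0.005	21.0
Q3TYD6	Serine/threonine-protein kinase LMTK2	1.13	0.009	8.2
O54782	Epididymis-specific alpha-mannosidase precursor	1.08	0.012	7.1
Q9DC29	Mitochondrial ATP-binding cassette sub-family B member 6	1.06	0.013	14.8
Q9D1R9	60S ribosomal protein L34	1.05	0.015	23.1
P01902	H-2 class I histocompatibility antigen, K-D alpha chain precursor	0.99	0.021	26.4
P12970	60S ribosomal protein L7a	0.98	0.023	33.1
Q09200	Beta-1,4 N-acetylgalactosaminyltransferase 1	0.98	0.023	20.1
Q924S8	Sprouty-related, EVH1 domain-containing protein 1	0.97	0.024	11.3
P31996	Macrosialin precursor (CD68)	0.97	0.025	5.5
P35979	60S ribosomal protein L12	0.92	0.033	15.2
Q61033	Lamina-associated polypeptide 2 (Lap2)	0.88	0.041	4.2
P42082	T-lymphocyte activation antigen CD86	0.87	0.044	22.3
Q61735	Leukocyte surface antigen CD47	0.87	0.044	8.9
P62270	40S ribosomal protein S18	0.85	0.048	17.1
P58681	Toll-like receptor 7 precursor	-3.89	0.000	15.0
P24063	Integrin alpha-L precursor (CD11a)	-2.37	0.000	8.1
Q3UQJ7	DnaJc 13 homolog, N-terminal fragment RME-8	-2.24	0.000	13.1
Q8BNL1	DnaJc 13 homolog, C-terminal fragment RME-8	-2.07	0.000	6.0
P62814	Vacuolar ATP synthase subunit B, brain isoform	-2.00	0.000	35.4
Q8BVE3	Vacuolar ATP synthase subunit H	-1.98	0.000	25.3
P20152	Vimentin	-1.94	0.000	30.0
P50516	Vacuolar ATP synthase catalytic subunit A	-1.92	0.000	48.8
P50518	Vacuolar ATP synthase subunit E 1	-1.91	0.000	34.5
Q9Z1G3	Vacuolar ATP synthase subunit C 1	-1.90	0.000	24.1
A1L314	Macrophage expressed protein (Mpeg1)	-1.77	0.000	8.4
Q69ZN7	Myoferlin	-1.76	0.000	32.6
P57746	Vacuolar ATP synthase pump subunit D	-1.49	0.000	29.6
P47738	Aldehyde dehydrogenase, mitochondrial precursor	-1.41	0.000	37.0
O89001	Carboxypeptidase D precursor	-1.34	0.001	5.3
Q3U829	Uncharacterized protein	-1.29	0.001	2.5
Q8R4Y4	Stabilin-1 precursor	-1.12	0.005	1.8
P70290	55 kDa erythrocyte membrane protein (p55)	-1.12	0.005	10.1
Q80VQ0	Aldehyde dehydrogenase 3B1	-1.11	0.005	22.6
Q7TPR4	Alpha-actinin-1	-1.06	0.008	26.9
P17439	Glucosylceramidase precursor	-1.05	0.008	15.1
Q9CPN8	Insulin-like growth factor 2 mRNA-binding protein 3	-0.96	0.015	26.4
Q99K70	Ras-related GTP-binding protein C	-0.93	0.019	8.8
P30204	Macrophage scavenger receptor types I and II (CD204)	-0.92	0.020	32.1
Q03265	ATP synthase subunit alpha, mitochondrial precursor	-0.92	0.020	32.7
P60122	RuvB-like 1	-0.92	0.020	9.0
O35474	EGF-like repeat and discoidin I-like domain-containing protein 3 precursor	-0.90	0.023	5.8
Q91WB7	Ubiquitin domain-containing protein 1	-0.90	0.023	10.6
P55302	Alpha-2-macroglobulin receptor-associated protein precursor	-0.87	0.028	9.7
Q91VR2	ATP synthase subunit gamma, mitochondrial precursor	-0.84	0.034	8.4
Q8BFR5	Elongation factor Tu, mitochondrial precursor	-0.82	0.038	5.8
Q8BIJ7	RUN and FYVE domain-containing protein 1 (Rabip4)	-0.82	0.040	13.3
Q3UH76	plexin B2	-0.80	0.043	17.8
O08599	Syntaxin-binding protein 1	-0.80	0.043	9.9
Q9WV54	Acid ceramidase precursor	-0.79	0.046	18.3
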