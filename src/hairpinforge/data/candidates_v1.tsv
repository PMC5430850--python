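pmid	pdb_id	chain_length	sequence	g_score	excluded	exclusion_reason
8069626	134D	31	TCCTCCTTTTTTAGGAGGATTTTTTGGTGGT	15	Yes	Triplex
8069626	135D	31	TCCTCCTTTTTTAGGAGGATTTTTTGGTGGT	15	Yes	Triplex
8069626	136D	31	TCCTCCTTTTTTAGGAGGATTTTTTGGTGGT	15	Yes	Triplex
7613864	184D	7	GCATGCT	0	Yes	Dimer Quadruplex
9737926	1A8N	12	GGGCTTTTGGGC	0	Yes	Dimer Quadruplex
9737927	1A8W	12	GGGCTTTTGGGC	0	Yes	Dimer Quadruplex
9092659	1AC7	16	ATCCTAGTTATAGGAT	0	No	N/A
9398169	1AO9	13	GAGAGAXTCTCTC	0	Yes	Complexed with non-protein ligand
7664126	1AU6	8	CATGCATG	0	Yes	Complexed with non-protein ligand
9384529	1AW4	27	ACCTGGGGGAGTATTGCGGAGGAAGGT	0	Yes	Complexed with non-protein ligand
9000625	1BJH	11	GTACAAAGTAC	0	No	N/A
9367776	1C11	11	TCCCGTTTCCA	0	Yes	Dimer Quadruplex
12371856	1CS7	13	GUTTTGXCAAAAC	0	Yes	Complexed with non-protein ligand
2299669	1D16	16	CGCGCGTTTTCGCGCG	0	Yes	Z-DNA
10653638	1DB6	22	CGACCAACGTGTCGCCTGGTCG	0	Yes	Complexed with non-protein ligand
10756190	1DGO	18	AGGATCCTUTTGGATCCT	0	No	N/A
N/A	1ECU	19	GCGCGAAACTGTTTCGCGC	0	No	N/A
10924101	1EN1	18	GTCCCTGTTCGGGCGCCA	0	No	N/A
11090280	1EZN	36	CGTGCACCCGCTTGCGGCGACTTGTCGTTGTGCACG	0	Yes	Three way junction
11790144	1FV8	11	TATCATCGATA	0	Yes	Non-nucleotide modified residues
11352724	1G5L	6	CCAAAG	0	Yes	Complexed with non-protein ligand
11352724	1GJ2	6	CCAAAG	0	Yes	Complexed with non-protein ligand
11952790	1IDX	18	AGGATCCTTUTGGATCCT	0	No	N/A
11952790	1II1	18	AGGATCCUTTTGGATCCT	0	No	N/A
11843626	1JU0	23	CTTGCTGAAGCGCGCACGGCAAG	0	Yes	Dimer
11843626	1JUA	23	CTTGCTGAAGCGCGCACGGCAAG	0	Yes	Dimer
11991355	1JVE	27	CCTAATTATAACGAAGTTATAATTAGG	0	No	N/A
12449414	1KR8	7	GCGAAGC	0	No	N/A
11895443	1L0R	14	ACGAAGTGCGAAGC	0	Yes	Complexed with non-protein ligand
11849039	1LA8	13	CGCGGTGTCCGCG	0	No	N/A
11849039	1LAE	13	CGCGGTPTCCGCG	0	Yes	Non-nucleotide modified residues
11849038	1LAI	13	CGCGGTGTCCGCG	0	Yes	Duplex
11849038	1LAQ	13	CGCGGTPTCCGCG	0	Yes	Duplex
11849038	1LAS	13	CGCGGTPTCCGCG	0	Yes	Duplex
12560479	1MF5	7	GCATGCT	0	Yes	Dimer Quadruplex
12564921	1MP7	10	GCCAGAGAGC	0	Yes	Complexed with non-protein ligand
12755609	1NGO	27	CTCTTTTTGTAAGAAATACAAGGAGAG	0	No	N/A
12755609	1NGU	27	CTCTCCTTGTATTTCTTACAAAAAGAG	0	No	N/A
12758081	1P0U	13	GCATCGACGATGC	0	No	N/A
8525381	1PNN	24	GAAGAAGAG	0	Yes	Triplex
12449414	1PQT	7	GCGAAGC	0	No	N/A
12952463	1PUY	13	GTTTTGXCAAAAC	0	Yes	Complexed with non-protein ligand
10481034	1QE7	22	CTAGAGGATCCTTTUGGATCCT	0	No	N/A
N/A	1QYK	7	GCATGCT	0	Yes	Dimer Quadruplex
N/A	1QYL	7	GCATGCT	0	Yes	Dimer Quadruplex
15199171	1SNJ	36	CGTGCAGCGGCTTGCCGGCACTTGTGCTTCTGCACG	0	Yes	Three way junction
14684897	1UE2	9	GCGAAAGCT	0	Yes	Duplex
14684897	1UE3	8	GCGAAAGC	0	Yes	Duplex
8901550	1XUE	17	GTGGAATGCAATGGAAC	0	No	N/A
7583654	1ZHU	10	CAATGCAATG	0	No	N/A
8548453	229D	17	CCAGACUGAAGAUCUGG	0	Yes	Non-nucleotide modified residues
9818148	2ARG	30	TGACCAGGGCAAACGGTAGGTGAGTGGTCA	18	Yes	Complexed with non-protein ligand
16620121	2AVH	11	GGGGTTTGGGG	0	Yes	G-Quadruplex
N/A	2F1Q	42	GCACTGCATCCTTGGACGCTTGCGCCACTTGTGGTGCAGTGC	0	Yes	Four way junction
16866556	2GKU	24	TTGGGTTAGGGTTAGGGTTAGGGA	42	Yes	G-Quadruplex
N/A	2K67	17	TTAATTTNNNAAATTAA	0	Yes	Non-nucleotide modified residues
N/A	2K68	17	TTAATTTNNNAAATTAA	0	Yes	Non-nucleotide modified residues
N/A	2K69	17	TTAATTTNNNAAATTAA	0	Yes	Non-nucleotide modified residues
19374420	2K71	8	GCGAAAGC	0	No	N/A
19321501	2K8Z	8	TCGTTGCT	0	Yes	Dimer
19070621	2KAZ	13	GGGACGTAGTGGG	0	Yes	Dimer Quadruplex
21410196	2L13	13	TATTATXATAATA	0	Yes	Non-nucleotide modified residues
22129448	2L5K	23	CAGTTGATCCTTTGGATACCCTG	0	No	N/A
22507054	2LO5	12	GGCCGCAGTGCC	0	No	N/A
22507054	2LO8	10	GCCGCAGTGC	0	No	N/A
22507054	2LOA	10	GCCGCAGTGC	0	Yes	Complexed with non-protein ligand
22798499	2LSC	12	CGCGAAUUCGCG	0	Yes	Complexed with non-protein ligand
23794476	2M8Y	15	CGCGAAGCATTCGCG	0	No	N/A
23794476	2M8Z	27	GGTTGGCGCGAAGCATTCGCGGGTTGG	9	Yes	Quadruplex Duplex Hybrid
23794476	2M90	32	GCGCGAAGCATTCGCGGGGAGGTGGGGAAGGG	21	Yes	Quadruplex Duplex Hybrid
23794476	2M91	30	GGGAAGGGCGCGAAGCATTCGCGAGGTAGG	7	Yes	Quadruplex Duplex Hybrid
23794476	2M92	34	AGGGTGGGTGCTGGGGCGCGAAGCATTCGCGAGG	17	Yes	Quadruplex Duplex Hybrid
23794476	2M93	32	TTGGGTGGGCGCGAAGCATTCGCGGGGTGGGT	29	Yes	Quadruplex Duplex Hybrid
8658168	2NEO	19	CCCGATGCXGCAATTCGGG	0	Yes	Complexed with non-protein ligand
17362008	2O3M	22	AGGGAGGGCGCTGGGAGGAGGG	39	Yes	G-Quadruplex
17388570	2OEY	25	CCATCGTCTACCTTTGGTAGGATGG	0	Yes	Complexed with non-protein ligand
9020982	2PIK	23	CACTCCTGGTTTTTCCAGGAGTG	0	Yes	Complexed with non-protein ligand
18515837	2VAH	18	AGGATCCTUTTGGATCCT	0	No	N/A
18515837	2VAI	18	AGGATCCTUTTGGATCCT	0	No	N/A
22287624	3QXR	22	AGGGAGGGCGCUGGGAGGAGGG	39	Yes	G-Quadruplex
N/A	3T86	7	GCATGCT	0	Yes	Complexed with non-protein ligand
22409313	4DKZ	12	CGCGAAXXCGCG	0	Yes	Non-nucleotide modified residues
8107090	148D	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
9384529	1AW4	27	ACCTGGGGGAGTATTGCGGAGGAAGGT	14	Yes	Complexed with non-protein ligand
9799703	1BUB	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
10756199	1C32	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
10756199	1C34	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
10756199	1C35	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
10756199	1C38	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
10653638	1DB6	22	CGACCAACGTGTCGCCTGGTCG	0	Yes	Complexed with non-protein ligand
8757801	1QDF	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
8757801	1QDH	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
15214802	1RDE	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
15637158	1Y8D	16	GGGGTGGGAGGAGGGT	21	Yes	Dimer Quadruplex
9818148	2ARG	30	TGACCAGGGCAAACGGTAGGTGAGTGGTCA	18	Yes	Complexed with non-protein ligand
17145716	2IDN	15	GGTTGGTGTGGTTGG	20	Yes	G-Quadruplex
23935071	2M53	25	TGTGGGGGTGGACGGGCCGGGTAGA	21	Yes	G-Quadruplex
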