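# Photosystem I electron-transfer chlorophyll annotations for the nine
# reference entries.  Columns: pdb_id, role, chain, res_seq, res_name,
# axial_chain, axial_res.  axial_res is the one-letter residue code plus
# sequence number of the residue providing the Mg axial ligand (PsaA -> chain
# A, PsaB -> chain B).
pdb_id	role	chain	res_seq	res_name	axial_chain	axial_res
1JB0	P700_A	A	1011	CLA	A	H680
1JB0	P700_B	B	1021	CLA	B	H660
1JB0	A_-1A	B	1012	CLA	B	N591
1JB0	A_-1B	A	1022	CLA	A	N604
1JB0	A_0A	A	1013	CLA	A	M688
1JB0	A_0B	B	1023	CLA	B	M668
1JB0	A_CA	A	1140	CLA	A	H734
1JB0	A_CB	B	1239	CLA	B	H718
5OY0	P700_A	A	1011	CLA	A	H676
5OY0	P700_B	B	1021	CLA	B	H651
5OY0	A_-1A	A	1012	CLA	B	N582
5OY0	A_-1B	B	1022	CLA	A	N600
5OY0	A_0A	A	1013	CLA	A	M684
5OY0	A_0B	B	1023	CLA	B	M659
5OY0	A_CA	A	1140	CLA	A	H730
5OY0	A_CB	B	1239	CLA	B	H709
6HQB	P700_A	A	1011	CLA	A	H676
6HQB	P700_B	B	1021	CLA	B	H651
6HQB	A_-1A	A	1012	CLA	B	N582
6HQB	A_-1B	B	1022	CLA	A	N600
6HQB	A_0A	A	1013	CLA	A	M684
6HQB	A_0B	B	1023	CLA	B	M659
6HQB	A_CA	A	1140	CLA	A	H730
6HQB	A_CB	B	1239	CLA	B	H709
6JO6	P700_A	A	801	CL0	A	H676
6JO6	P700_B	B	802	CLA	B	H655
6JO6	A_-1A	A	803	CLA	B	N586
6JO6	A_-1B	A	854	CLA	A	N601
6JO6	A_0A	A	802	CLA	A	M684
6JO6	A_0B	B	803	CLA	B	M663
6JO6	A_CA	A	842	CLA	A	H730
6JO6	A_CB	B	840	CLA	B	H713
6KMW	P700_A	A	801	CL0	A	H689
6KMW	P700_B	B	803	CLA	B	H662
6KMW	A_-1A	B	804	CLA	B	N593
6KMW	A_-1B	B	801	CLA	A	N613
6KMW	A_0A	B	802	CLA	A	M697
6KMW	A_0B	B	805	CLA	B	M670
6KMW	A_CA	A	841	CLA	A	H743
6KMW	A_CB	B	841	CLA	B	H720
6KMX	P700_A	A	801	CL0	A	H709
6KMX	P700_B	B	801	CLA	B	H664
6KMX	A_-1A	B	802	CLA	B	N595
6KMX	A_-1B	A	802	CLA	A	N633
6KMX	A_0A	A	803	CLA	A	M717
6KMX	A_0B	B	803	CLA	B	M672
6KMX	A_CA	A	843	CLA	A	H763
6KMX	A_CB	B	840	CLA	B	H721
6PNJ	P700_A	A	1011	CL0	A	H713
6PNJ	P700_B	B	1021	CLA	B	H661
6PNJ	A_-1A	A	1012	CLA	B	N592
6PNJ	A_-1B	B	1022	CLA	A	N637
6PNJ	A_0A	A	1013	CLA	A	M721
6PNJ	A_0B	B	1023	CLA	B	M669
6PNJ	A_CA	A	1140	CLA	A	H767
6PNJ	A_CB	B	1239	CLA	B	H718
7COY	P700_A	A	3101	G9R	A	H678
7COY	P700_B	B	3003	CL7	B	H657
7COY	A_-1A	B	3002	CL7	B	N588
7COY	A_-1B	A	3103	CL7	A	N602
7COY	A_0A	A	3102	PHO	A	M686
7COY	A_0B	B	3004	PHO	B	L665
7COY	A_CA	A	3143	CL7	A	H732
7COY	A_CB	B	3026	CL7	B	H715
5ZJI	P700_A	A	801	CL0	A	H675
5ZJI	P700_B	B	802	CLA	B	H654
5ZJI	A_-1A	A	803	CLA	B	N585
5ZJI	A_-1B	A	854	CLA	A	N599
5ZJI	A_0A	A	802	CLA	A	M683
5ZJI	A_0B	B	803	CLA	B	M662
5ZJI	A_CA	A	842	CLA	A	H729
5ZJI	A_CB	B	840	CLA	B	H712
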