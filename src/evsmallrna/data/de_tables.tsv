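source_table	sample	feature	base_mean	log2fc	note
T1_ASC_cells	ASC cells	hsa-let-7i-3p	479	-1.6	
T1_ASC_cells	ASC cells	hsa-miR-146b-5p	20821	2.1	
T1_ASC_cells	ASC cells	hsa-miR-1908-5p	39	1.5	
T1_ASC_cells	ASC cells	hsa-miR-210-3p	1191	-2.8	
T1_ASC_cells	ASC cells	hsa-miR-210-5p	89	-2.9	
T1_ASC_cells	ASC cells	hsa-miR-222-5p	151	-1.5	
T1_ASC_cells	ASC cells	hsa-miR-335-3p	1681	-4.0	
T1_ASC_cells	ASC cells	hsa-miR-335-5p	1248	-3.5	
T1_ASC_cells	ASC cells	hsa-miR-6842-3p	281	2.2	
T1_ASC_cells	ASC cells	hsa-miR-95-3p	172	6.2	
T1_BMSC_cells	BMSC cells	hsa-let-7i-3p	427	-1.0	
T1_BMSC_cells	BMSC cells	hsa-miR-146b-5p	3630	-1.1	
T1_BMSC_cells	BMSC cells	hsa-miR-1908-5p	31	1.7	
T1_BMSC_cells	BMSC cells	hsa-miR-210-3p	1236	-1.7	
T1_BMSC_cells	BMSC cells	hsa-miR-210-5p	104	-1.5	
T1_BMSC_cells	BMSC cells	hsa-miR-222-5p	443	1.0	
T1_BMSC_cells	BMSC cells	hsa-miR-335-3p	3536	-2.6	
T1_BMSC_cells	BMSC cells	hsa-miR-335-5p	2835	-1.7	
T1_BMSC_cells	BMSC cells	hsa-miR-6842-3p	65	3.8	
T1_BMSC_cells	BMSC cells	hsa-miR-95-3p	21	5.0	
T1_ASC_pairs	ASC cells	hsa-miR-125b-2-3p	808	1.1	
T1_ASC_pairs	ASC cells	hsa-miR-425-5p	1440	1.1	
T1_ASC_pairs	ASC-EVs	hsa-miR-425-5p	15	-4.8	
T1_ASC_pairs	ASC-EVs	hsa-miR-125b-2-3p	29	4.7	
T1_BMSC_EV_pairs	BMSC cells	hsa-miR-133a-3p	120	1.3	
T1_BMSC_EV_pairs	BMSC cells	hsa-miR-146a-5p	86	-1.1	
T1_BMSC_EV_pairs	BMSC cells	hsa-miR-146b-5p	3630	-1.1	
T1_BMSC_EV_pairs	BMSC cells	hsa-miR-155-5p	871	-1.4	
T1_BMSC_EV_pairs	BMSC cells	hsa-miR-378a-3p	2747	-1.4	
T1_BMSC_EV_pairs	BMSC cells	hsa-miR-483-5p	168	8.5	
T1_BMSC_EV_pairs	BMSC-EVs	hsa-miR-133a-3p	15	7.1	
T1_BMSC_EV_pairs	BMSC-EVs	hsa-miR-146a-5p	26	-3.9	
T1_BMSC_EV_pairs	BMSC-EVs	hsa-miR-146b-5p	1450	-2.2	
T1_BMSC_EV_pairs	BMSC-EVs	hsa-miR-155-5p	183	-1.1	
T1_BMSC_EV_pairs	BMSC-EVs	hsa-miR-378a-3p	1026	-1.9	
T1_BMSC_EV_pairs	BMSC-EVs	hsa-miR-483-5p	20	7.5	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-10b-5p	172238	-1.1	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-10a-5p	71894	-2.0	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-22-3p	44127	1.3	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-191-5p	30963	-1.4	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-486-5p	22431	-1.2	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-100-5p	20117	-1.1	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-146b-5p	1450	-2.2	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-378a-3p	1026	-1.9	
T2_BMSC_EVs	BMSC-EVs	hsa-let-7d-5p	908	1.2	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-30c-5p	370	1.3	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-155-5p	183	-1.1	
T2_BMSC_EVs	BMSC-EVs	hsa-let-7d-3p	168	1.3	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-12136	94	-2.3	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-1910-5p	82	9.5	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-4516	81	-3.0	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-877-5p	42	2.0	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-146a-5p	26	-3.9	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-483-5p	20	7.5	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-133a-3p	15	7.1	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-3180-3p	14	-7.6	
T2_BMSC_EVs	BMSC-EVs	hsa-miR-34b-5p	10	6.5	
T3_ASC_EVs	ASC-EVs	hsa-miR-769-5p	20	-3.7	
T3_ASC_EVs	ASC-EVs	hsa-miR-425-5p	15	-4.8	
T3_ASC_EVs	ASC-EVs	hsa-miR-125b-2-3p	29	4.7	
T3_ASC_EVs	ASC-EVs	hsa-miR-145-5p	97	-5.9	
T5_BMSC_EVs	BMSC-EVs	Ser-ACT	15	5.4	fragment
T5_BMSC_EVs	BMSC-EVs	Ser-GCT	753	2.0	fragment
T5_BMSC_EVs	BMSC-EVs	Sup-TTA	35	3.9	fragment
T5_BMSC_EVs	BMSC-EVs	Phe-GAA	826	2.2	fragment
T5_BMSC_EVs	BMSC-EVs	Ile-AAT	545	2.8	fragment
T5_BMSC_EVs	BMSC-EVs	Lys-TTT	4439	1.4	fragment
T5_BMSC_EVs	BMSC-EVs	Gly-CCC	236570	-2.9	halve
T5_BMSC_EVs	BMSC-EVs	Leu-TAG	393	1.9	fragment
T5_BMSC_EVs	BMSC-EVs	Gly-GCC	804325	-2.8	halve
T5_BMSC_EVs	BMSC-EVs	His-GTG	22356	-2.5	halve
T5_BMSC_EVs	BMSC-EVs	Thr-CGT	234	2.1	fragment
T5_ASC_EVs	ASC-EVs	Arg-CCG	204	-3.5	halve
T5_ASC_EVs	ASC-EVs	Phe-GAA	826	-3.0	fragment
T5_ASC_EVs	ASC-EVs	Asn-GTT	147	2.8	fragment
T5_ASC_EVs	ASC-EVs	Ile-AAT	545	2.6	fragment
T5_ASC_EVs	ASC-EVs	Ala-TGC	1188	2.7	fragment
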