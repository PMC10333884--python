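bait	position_label	peptide	kd_wt	kd_pm	kd_phos	pes	p_value	representative
AP2 mu2	p-1	BAIAPL1_392-407	1.29	0.49	0.93	1.2	0.095	1
AP2 mu2	p+8	PCBP1_179-194	3.7	2.05	0.67	1	0.15	1
Clathrin NTD	p+5	HURP_832-846	134	23	<3	12	0.000009	1
GABARAPL2	p-4	ATG4C_444-458	0.8	1.8	0.1	4.3	0.0025	1
GABARAPL2	p+3	TBK1_164-179	19	12.4	2.8	1	0.11	1
GABARAPL2	p+6	DLGAP4_907-922	174	260	150	-3.9	0.00047	1
GGA1 VHS	p-3	JUN_59-73	470	450	1900	3.6	0.023	1
GGA1 VHS	p+1	GTSE1_145-160	96	199	640	9	0.00012	1
GGA1 VHS	p+2	RNF11_6-21	420	1000	31	4.9	0.009	1
KPNA4 ARM major	p-4	CDC25A_114-125	8.8	0.75	0.63	10	0.000006	1
KPNA4 ARM major	p+3	SQSTM1_258-272	0.24	5.3	50	-3	0.0096	1
KPNA4 ARM major	p+5	RANBP3_114-129	0.15	0.80	1.13	-7	0.00012	1
KPNA4 ARM major	p+6	RANBP3_114-129	0.15	0.14	0.22	-3.1	0.077	1
KPNA4 ARM minor	p-4	CDC25A_114-127	0.200	2.3	2.8	10	0.000006	0
KPNA4 ARM minor	p+3	SQSTM1_258-272	14.0	41	248	-3	0.0096	0
KPNA4 ARM minor	p+5	RANBP3_114-129	68	61	167	-7	0.00012	0
KPNA4 ARM minor	p+6	RANBP3_114-129	68	80	20	-3.1	0.077	0
MAP1LC3A	p-4	ATG4C_444-458	5.2	3.1	1.3	2.3	0.015	1
MAP1LC3A	p-1	TPD52L2_91-106	226	78	20.6	14	0.000000099	1
MAP1LC3A	p+3	TBK1_164-179	8.4	4.8	0.89	3.2	0.0061	1
MAP1LC3B	p-4	ATG4C_444-458	7.1	4.6	1.9	6	0.00063	1
MAP1LC3B	p-1	TPD52L2_91-106	760	225	61	3	0.012	1
MAP1LC3B	p+3	TBK1_164-179	10.5	2.1	1.3	5.1	0.00047	1
PDCD6IP Alix V	p-5	OTUD5_507-522	68	88	116	0.66	0.34	1
PDCD6IP Alix V	p+6	FOXK1_212-227	25	13	13	2.9	0.04	1
RANBP2 RanBD4	p-1	INTS6_145-159	334	1075	733	-4	0.0044	1
RANBP2 RanBD4	p+4	DHX38_260-275	1500	470	167	3	0.04	1
SNX27 PDZ	p-3	DAXX_606-616	300	23	96	6	0.00063	1
SNX27 PDZ	p-1	CDC25C_30-44	111	680	395	-6	0.00063	1
TSG101 UEV	p-1	PIP4P2_17-32	14	18	16	-14	0.0000002	1
TSG101 UEV	p+5	GJA1_269-283	232	115	209	6	0.0013	1
TSG101 UEV	p+2	PDCD6IP_711-725	16	n.b.	n.b.	-15	0.00000004	1
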