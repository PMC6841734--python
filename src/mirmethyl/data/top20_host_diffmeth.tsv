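gene	probe_id	resident_mirna	coeff	p_category	q_value
CIT	cg03339668	miR-1178 (sense; exonic)	3.0116	*	0.13416
SREBF1	cg09796270	miR-33B (sense; intronic)	2.3618	*	0.08757
C9orf3	cg21189849	miR-23B (sense; intronic)	2.2652	*	0.18803
SLIT2	cg19940312	miR-218-1 (sense; intronic)	2.1981	*	0.36809
WHSC2	cg00248861	miR-943 (sense; exonic)	2.0870	*	0.52318
WWP2	cg26736200	miR-1205 (sense; intronic)	2.0818	*	0.21430
MCM7	cg22420044	miR-25 (sense; intronic)	1.6960	**	0.00692
BCAR3	cg17274827	miR-760 (antisense; intronic)	1.6260	*	0.40336
AKT2	cg15701203	miR-641 (sense; intronic)	1.6229	*	0.80941
DNM3	cg06267617	miR-199A1 (antisense; intronic)	1.5988	**	0.03039
AATK	cg16067628	miR-657 (sense; intronic)	1.5947	**	0.00751
LRP1	cg20029881	miR-1228 (sense; intronic)	1.5654	*	0.26971
HOXB3	cg12910797	miR-10A (sense; intronic)	1.5616	**	0.02261
GNAI3	cg08644463	miR-197 (sense; exonic)	1.2895	*	0.60953
MSLNL	cg02266878	miR-662 (antisense; exonic)	-1.2366	*	0.56317
FBXL18	cg09554310	miR-589 (sense; intronic)	-1.2813	*	0.19659
WDR82	cg12048331	miR-LET7G (sense; intronic)	-1.3231	*	0.91190
CCPG1	cg12392104	miR-628 (sense; intronic)	-1.4477	**	0.00787
RUNX1	cg00291213	miR-802 (antisense; intronic)	-1.5569	*	0.55194
PVT1	cg02901522	miR-1205 (sense; intronic)	-3.1615	*	0.05741
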