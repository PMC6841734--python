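gene	probe_id	host	coeff	p_category	q_value
miR-199B	cg13718827	DNM1 (antisense; intronic)	2.3595	***	0.00128
miR-33B	cg04805065	SREBF1 (sense; intronic)	2.1974	*	0.12825
miR-874	cg18251187	KLHL3 (sense; intronic)	2.0571	**	0.00944
miR-1286	cg08221669	RTN4R (sense; intronic)	1.7488	**	0.02761
miR-1306	cg20689730	DGCR8 (sense; exonic)	1.6852	**	0.03932
miR-130A	cg10512089	intergenic	1.6548	*	0.09226
miR-320B1	cg25023761	intergenic	1.5556	**	0.02459
miR-641	cg26620021	AKT2 (sense; intronic)	1.5535	**	0.03169
miR-942	cg19582647	TTF2 (sense; intronic)	1.5362	*	0.82808
miR-499	cg11231913	MYH7B (sense; intronic)	1.5245	***	0.00004
miR-30B	cg25964744	intergenic	1.4986	*	0.75198
miR-184	cg23721598	ANKRD34C-AS1 (antisense; intronic)	1.4823	**	0.02005
miR-194-2	cg24803202	MIR194-2HG (sense; exonic)	1.4674	*	0.42089
miR-25	cg22638766	MCM7 (sense; intronic)	1.4593	*	0.13411
miR-662	cg26775123	MSLNL (antisense; exonic)	1.4426	*	0.80350
miR-1471	cg06046580	intergenic	1.3949	*	0.08720
miR-199A1	cg18544365	DNM2 (antisense; intronic)	1.3434	*	0.26307
miR-320D1	cg23483562	intergenic	1.2870	*	0.60071
miR-1182	cg20821842	FAM89A (sense; exonic)	-3.0805	**	0.00667
miR-193A	cg08667128	intergenic	-1.4483	***	0.00030
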