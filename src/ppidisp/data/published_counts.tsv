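dataset	property_name	common_total	common_disrupt_T	common_disrupt_P	disease_total	disease_disrupt_T	disease_disrupt_P
Y2H	strength	1080	3	13	348	7	36
Lit	strength	2867	27	29	1572	51	68
Y2H	temporal	1080	7	9	347	18	24
Lit	temporal	2867	16	40	1571	57	61
Y2H	spatial_expr	1075	4	7	336	12	19
Lit	spatial_expr	2859	19	29	1563	61	49
Y2H	spatial_promoter	1080	3	13	345	23	17
Lit	spatial_promoter	2862	19	32	1570	57	60
Y2H	balance_time	1080	1	15	347	8	34
Lit	balance_time	2867	12	44	1570	32	85
Y2H	balance_space_expr	1080	11	5	343	21	17
Lit	balance_space_expr	2866	32	23	1567	58	56
Y2H	balance_space_promoter	1080	6	10	344	22	17
Lit	balance_space_promoter	2862	22	29	1568	48	67
Y2H	exclusivity_1_4	1079	4	2	348	24	8
Lit	exclusivity_1_4	2865	30	10	1566	50	34
Y2H	exclusivity_ge5	1079	9		348	11
Lit	exclusivity_ge5	2865	14		1566	29
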