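status	case_index	age_years	gestational_age	z_chr21	ff_pct
true_positive	1	36	16	10.81	13.91
true_positive	2	38	17+4	13.40	14.43
true_positive	3	40	25+4	24.83	28.03
true_positive	4	47	14	10.46	16.07
true_positive	5	38	14+5	13.35	20.06
true_positive	6	46	21+3	7.85	11.34
true_positive	7	41	13+4	3.83	4.88
true_positive	8	36	15+4	9.77	12.55
true_positive	9	27	17+5	6.43	12.73
true_positive	10	29	12+3	11.64	16.20
true_positive	11	28	13+5	13.51	15.83
true_positive	12	41	13+6	6.79	12.22
true_positive	13	23	15+6	12.44	14.80
true_positive	14	40	18+4	9.90	14.38
false_positive	1	26	31	3.81	13.91
false_positive	2	30	18+1	3.04	24.9
false_negative	1	35	17+3	1.78	8.13
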