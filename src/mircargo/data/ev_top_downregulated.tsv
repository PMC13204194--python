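gene_symbol	entrez_id	fold_change	p_value
NMT1	4836	4.68e-4	2.07e-3
RPL17	6139	3.80e-3	5.17e-3
UBA52	7311	5.25e-3	2.85e-2
PAICS	10606	7.41e-3	4.15e-3
UBALD2	283991	1.20e-2	8.77e-4
NCOR2	9612	1.62e-2	1.39e-3
TSEN34	79042	2.29e-2	1.99e-4
ACTN1	87	2.45e-2	1.12e-5
EEF1D	1936	2.75e-2	8.44e-3
CDC34	997	3.31e-2	4.61e-3
SNRNP70	6625	3.89e-2	4.23e-2
PSMC3	5702	4.47e-2	1.71e-2
PTCD3	55037	4.47e-2	5.95e-3
CDKN1A	1026	4.90e-2	2.31e-2
KIFC3	3801	5.50e-2	3.59e-2
KLHL21	9903	5.62e-2	1.56e-3
NTAQ1	55093	6.92e-2	2.27e-3
S100A16	140576	7.08e-2	1.43e-5
ALDOA	226	7.08e-2	7.90e-3
CMTM3	123920	7.24e-2	2.36e-4
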