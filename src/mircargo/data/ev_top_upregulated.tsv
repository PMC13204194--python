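gene_symbol	entrez_id	fold_change	p_value
RNY1	6084	3.16e10	1.42e-12
RPL36	25873	3.98e3	4.14e-3
EIF4A1	1973	2.57e2	9.00e-5
WAC	51322	1.78e2	5.26e-3
LMNA	4000	1.48e2	1.95e-6
HNRNPH1	3187	8.71e1	1.97e-8
ACADVL	37	4.27e1	1.05e-2
HNRNPC	3183	4.07e1	1.93e-6
PPT1	5538	3.89e1	2.02e-2
STUB1	10273	2.88e1	2.31e-2
SNHG32	50854	2.45e1	3.59e-3
MKRN1	23608	2.29e1	6.21e-4
C11orf68	83638	2.24e1	2.46e-4
PSMD6	9861	2.14e1	2.12e-2
EIF2A	83939	2.00e1	2.19e-4
BOLA1	51027	1.95e1	1.48e-2
HLA-B	3106	1.95e1	3.49e-3
UPF2	26019	1.82e1	1.31e-3
PPP1R18	107987457	1.78e1	1.56e-2
RPL8	6132	1.58e1	2.45e-4
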