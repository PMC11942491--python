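locus_id	no_long_read	long_read	total
AR	1	0	1
ATN1	1	1	2
ATXN1	11	5	16
ATXN10	3	2	5
ATXN2	23	5	28
ATXN3	18	8	26
ATXN7	3	3	6
ATXN8OS	23	11	34
BEAN1	1	0	1
C9ORF72	6	3	9
CACNA1A	25	3	28
CNBP	1	3	4
CSTB	0	1	1
DIP2B	0	1	1
DMPK	1	0	1
FGF14	22	54	76
FMR1	6	10	16
FXN	29	13	42
GLS	0	1	1
HTT	2	7	9
JPH3	0	2	2
NOP56	0	3	3
NOTCH2NLC	0	1	1
PABPN1	2	1	3
PPP2R2B	2	0	2
RFC1	5	15	20
TBP	12	3	15
TCF4	1	0	1
ZFHX3	1	2	3
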