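gene	total	n_pass
MUC19	57	29
OBSCN	78	48
KMT2D	62	40
RYR1	51	39
MUC16	111	86
DNAH1	50	39
PLEC	51	40
DNHD1	39	31
MACF1	56	45
USH2A	37	30
UBR4	57	47
FAT4	35	29
SYNE2	53	44
LRP1	43	36
LRP1B	44	37
HECTD4	47	40
INTS1	30	26
SYNE1	87	78
RYR3	62	56
TTN	116	105
DMD	48	44
ATM	36	33
DNAH11	39	36
NBEAL1	26	24
MYCBP2	40	37
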