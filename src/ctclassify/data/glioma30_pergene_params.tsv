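gene	correlation	slope	intercept
IGFBP2	0.90	0.27	0.32
VMP1	0.04	0.05	2.87
MSN	0.81	0.36	1.00
TIMP1	0.92	0.30	-0.31
LGALS1	0.85	0.36	-0.56
CD63	0.51	0.20	-0.52
NES	0.69	0.26	0.69
CLIC1	0.86	0.43	0.34
TNC	0.04	-0.02	-0.63
TAGLN2	0.66	0.34	0.13
HES6	0.77	0.29	0.60
VEGF	0.78	0.25	-0.11
VIM	0.77	0.30	-0.52
LDHA	0.73	0.33	-0.12
RPIP8	0.81	0.26	0.71
IFITM3	0.85	0.38	-0.75
PPIB	0.60	0.29	-0.10
ALDOC	0.73	0.28	-0.09
ZYX	0.68	0.36	0.54
UPAR	0.84	0.36	1.48
LAMB2	0.43	0.23	0.62
RTN1	0.82	0.29	0.66
HMOX1	0.87	0.30	0.62
GM2A	0.51	0.24	0.62
S100A10	0.79	0.28	-0.18
BRSK2	0.68	0.22	1.21
MRCL3	0.73	0.30	0.38
GPX1	0.70	0.33	-0.41
SOD2	0.74	0.31	0.23
RHOC	0.11	-0.08	-0.06
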