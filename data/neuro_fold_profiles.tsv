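gene	expected	f1	f2	f3	f4	f5
VSNL1	-1	-1.20	-1.19	-0.28	-0.28	-0.50
NEFL	-1	-1.06	-0.72	-0.23	-0.42	-0.60
CCK	-1	-0.91	-1.12	-0.47	-0.23	-0.85
YWHAH	-1	-0.88	-0.38	-0.26	-0.17	-0.39
TUBA4A	-1	-0.75	-0.80	-0.45	-0.32	-0.23
YWHAB	-1	-0.73	-0.39	-0.72	-0.21	-0.40
NRN1	-1	-0.67	-0.65	-0.67	-0.31	-0.76
GUCY1B3	-1	-0.66	-0.64	-0.30	-0.22	-0.13
SCN1A	-1	-0.60	-1.05	-0.62	-0.36	-0.35
SYP	-1	-0.54	-0.62	-0.49	-0.26	-0.25
NDRG3	-1	-0.52	-0.58	-0.31	-0.17	-0.33
PPP2R2B	-1	-0.42	-0.66	-0.51	-0.25	-0.27
MDH2	-1	-0.42	-0.36	-0.28	-0.13	-0.12
DYNC1I1	-1	-0.39	-1.00	-0.71	-0.35	-0.47
RHOC	+1	0.30	0.39	1.03	0.73	0.74
SLC16A1	+1	0.35	0.36	0.69	0.48	0.20
MAPKAPK2	+1	0.40	0.32	0.51	0.37	0.23
CTSB	+1	0.43	0.79	0.80	0.86	0.57
DAB2	+1	0.47	1.05	0.94	0.58	0.29
CLU	+1	0.47	0.54	0.37	0.50	0.22
TBC1D2B	+1	0.51	0.32	0.42	0.18	0.76
ZFP36L1	+1	0.61	0.59	0.98	0.56	0.48
SREBF1	+1	0.63	0.90	0.57	0.36	0.46
MDFIC	+1	0.63	0.80	1.43	1.17	0.43
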