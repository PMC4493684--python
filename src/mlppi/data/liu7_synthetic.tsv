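# Synthetic stand-in for the 7-value amino-acid descriptor table used by
# sequence-deviation pair features. Columns are seven classical
# physicochemical properties (see hqi8_synthetic.tsv for sources).
aa	hydropathy	hydrophilicity	polarity	isoelectric_point	volume	helix_propensity	sheet_propensity
A	1.8	-0.5	8.1	6.00	91.5	1.42	0.83
C	2.5	-1.0	5.5	5.05	117.7	0.70	1.19
D	-3.5	3.0	13.0	2.77	124.5	1.01	0.54
E	-3.5	3.0	12.3	3.22	155.1	1.51	0.37
F	2.8	-2.5	5.2	5.48	203.4	1.13	1.38
G	-0.4	0.0	9.0	5.97	66.4	0.57	0.75
H	-3.2	-0.5	10.4	7.59	167.3	1.00	0.87
I	4.5	-1.8	5.2	6.02	168.8	1.08	1.60
K	-3.9	3.0	11.3	9.74	171.3	1.16	0.74
L	3.8	-1.8	4.9	5.98	167.9	1.21	1.30
M	1.9	-1.3	5.7	5.74	170.8	1.45	1.05
N	-3.5	0.2	11.6	5.41	135.2	0.67	0.89
P	-1.6	0.0	8.0	6.30	129.3	0.57	0.55
Q	-3.5	0.2	10.5	5.65	161.1	1.11	1.10
R	-4.5	3.0	10.5	10.76	202.0	0.98	0.93
S	-0.8	0.3	9.2	5.68	99.1	0.77	0.75
T	-0.7	-0.4	8.6	5.66	122.1	0.83	1.19
V	4.2	-1.5	5.9	5.96	141.7	1.06	1.70
W	-0.9	-3.4	5.4	5.89	237.6	1.08	1.37
Y	-1.3	-2.3	6.2	5.66	203.6	0.69	1.47
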