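# Synthetic stand-in for an 8-value "high quality index" amino-acid table.
# Columns are eight classical physicochemical/biochemical properties:
# Kyte-Doolittle hydropathy, Hopp-Woods hydrophilicity, Grantham polarity,
# isoelectric point, molecular weight (Da), Chothia residue volume (A^3),
# Chou-Fasman helix propensity, Chou-Fasman sheet propensity.
aa	hydropathy	hydrophilicity	polarity	isoelectric_point	molecular_weight	volume	helix_propensity	sheet_propensity
A	1.8	-0.5	8.1	6.00	89.09	91.5	1.42	0.83
C	2.5	-1.0	5.5	5.05	121.15	117.7	0.70	1.19
D	-3.5	3.0	13.0	2.77	133.10	124.5	1.01	0.54
E	-3.5	3.0	12.3	3.22	147.13	155.1	1.51	0.37
F	2.8	-2.5	5.2	5.48	165.19	203.4	1.13	1.38
G	-0.4	0.0	9.0	5.97	75.07	66.4	0.57	0.75
H	-3.2	-0.5	10.4	7.59	155.16	167.3	1.00	0.87
I	4.5	-1.8	5.2	6.02	131.17	168.8	1.08	1.60
K	-3.9	3.0	11.3	9.74	146.19	171.3	1.16	0.74
L	3.8	-1.8	4.9	5.98	131.17	167.9	1.21	1.30
M	1.9	-1.3	5.7	5.74	149.21	170.8	1.45	1.05
N	-3.5	0.2	11.6	5.41	132.12	135.2	0.67	0.89
P	-1.6	0.0	8.0	6.30	115.13	129.3	0.57	0.55
Q	-3.5	0.2	10.5	5.65	146.15	161.1	1.11	1.10
R	-4.5	3.0	10.5	10.76	174.20	202.0	0.98	0.93
S	-0.8	0.3	9.2	5.68	105.09	99.1	0.77	0.75
T	-0.7	-0.4	8.6	5.66	119.12	122.1	0.83	1.19
V	4.2	-1.5	5.9	5.96	117.15	141.7	1.06	1.70
W	-0.9	-3.4	5.4	5.89	204.23	237.6	1.08	1.37
Y	-1.3	-2.3	6.2	5.66	181.19	203.6	0.69	1.47
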