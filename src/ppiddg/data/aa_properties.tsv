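# Curated per-residue physicochemical properties (AAindex-style selection).
# hydrophobicity: Kyte-Doolittle; volume: A^3 (Zamyatnin); charge: formal at pH 7
# (His partial +0.1); polarity: Grantham; mass: residue mass (Da); pi: isoelectric point
# aa	hydrophobicity	volume	charge	polarity	mass	pi
A	1.8	88.6	0	8.1	71.08	6.00
R	-4.5	173.4	1	10.5	156.19	10.76
N	-3.5	114.1	0	11.6	114.10	5.41
D	-3.5	111.1	-1	13.0	115.09	2.77
C	2.5	108.5	0	5.5	103.14	5.07
Q	-3.5	143.8	0	10.5	128.13	5.65
E	-3.5	138.4	-1	12.3	129.12	3.22
G	-0.4	60.1	0	9.0	57.05	5.97
H	-3.2	153.2	0.1	10.4	137.14	7.59
I	4.5	166.7	0	5.2	113.16	6.02
L	3.8	166.7	0	4.9	113.16	5.98
K	-3.9	168.6	1	11.3	128.17	9.74
M	1.9	162.9	0	5.7	131.19	5.74
F	2.8	189.9	0	5.2	147.18	5.48
P	-1.6	112.7	0	8.0	97.12	6.30
S	-0.8	89.0	0	9.2	87.08	5.68
T	-0.7	116.1	0	8.6	101.10	5.60
W	-0.9	227.8	0	5.4	186.21	5.89
Y	-1.3	193.6	0	6.2	163.18	5.66
V	4.2	140.0	0	5.9	99.13	5.96
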