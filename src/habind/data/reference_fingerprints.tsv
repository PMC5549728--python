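# Reference binding-mode contact fingerprints for CD44-HABD residues
# previously identified as hyaluronan-binding in the literature.
# Values: percentage of frames with the residue within 0.6 nm of HA,
# mean +/- standard error over replicas; se 0.0 where no spread was reported.
residue	resid	crystallographic	crystallographic_se	parallel	parallel_se	upright	upright_se
N25	25	52.3	0.4	89.7	0.8	0.0	0.0
R29	29	2.1	0.7	1.1	1.1	11.2	11.2
K38	38	0.0	0.0	6.9	4.0	73.4	19.6
G40	40	9.5	1.5	100.0	0.0	39.5	23.6
R41	41	100.0	0.0	100.0	0.0	92.2	4.9
Y42	42	100.0	0.0	100.0	0.0	99.5	0.4
S43	43	6.0	6.0	66.1	17.6	98.0	1.3
I44	44	0.3	0.3	1.9	1.3	62.5	18.1
N57	57	0.0	0.0	0.0	0.0	20.4	20.4
K68	68	0.0	0.0	0.0	0.0	0.0	0.0
T76	76	95.1	0.9	2.1	2.1	51.1	17.6
C77	77	100.0	0.0	33.1	15.5	90.8	2.7
R78	78	100.0	0.0	100.0	0.0	92.8	3.3
Y79	79	100.0	0.0	85.2	8.2	93.4	3.2
G80	80	0.1	0.1	0.0	0.0	0.1	0.1
I88	88	100.0	0.0	10.3	3.4	78.7	9.0
N94	94	77.2	2.5	2.5	2.5	26.5	7.9
I96	96	100.0	0.0	16.5	7.5	96.9	0.8
C97	97	100.0	0.0	2.9	2.9	93.1	1.2
A98	98	100.0	0.0	41.9	15.3	89.4	4.7
A99	99	100.0	0.0	10.2	4.6	73.7	19.3
N100	100	13.2	2.5	1.5	1.2	30.7	12.8
N101	101	47.8	10.7	1.6	0.0	30.3	14.6
Y105	105	89.6	5.6	46.8	15.1	36.3	14.6
I106	106	35.3	13.7	18.9	10.2	0.5	0.5
L107	107	99.9	0.1	91.8	5.5	63.9	24.2
N110	110	92.1	5.7	100.0	0.0	13.6	7.4
D115	115	7.8	2.7	93.9	3.0	20.7	18.4
N120	120	0.0	0.0	0.0	0.0	17.5	17.5
N149	149	37.1	4.5	36.5	20.3	0.0	0.0
R150	150	88.0	2.7	37.0	28.5	0.0	0.0
D151	151	68.1	7.8	37.4	26.2	0.0	0.0
G152	152	61.9	8.6	65.2	20.3	0.0	0.0
R154	154	3.2	0.5	81.0	13.7	0.1	0.1
Y155	155	1.2	0.9	44.2	22.1	0.0	0.0
K158	158	0.0	0.0	17.0	11.9	35.9	18.2
R162	162	0.8	0.4	0.0	0.0	98.1	1.0
N164	164	10.7	7.6	0.3	0.1	68.1	18.8
E166	166	16.0	9.3	0.4	0.4	72.4	19.1
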