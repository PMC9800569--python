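chromosome	length_bp	centromere_start_bp	centromere_end_bp
1	248956422	121700000	125100000
2	242193529	91800000	96000000
3	198295559	87800000	94000000
4	190214555	48200000	51800000
5	181538259	46100000	51400000
6	170805979	58500000	62600000
7	159345973	58100000	62100000
8	145138636	43200000	47200000
9	138394717	42200000	45500000
10	133797422	38000000	41600000
11	135086622	51000000	55800000
12	133275309	33200000	37800000
13	114364328	16500000	18900000
14	107043718	16100000	18200000
15	101991189	17500000	20500000
16	90338345	35300000	38400000
17	83257441	22700000	27400000
18	80373285	15400000	21500000
19	58617616	24200000	28100000
20	64444167	25700000	30400000
21	46709983	10900000	13000000
22	50818468	13700000	17400000
X	156040895	58100000	63800000
Y	57227415	10300000	10600000
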