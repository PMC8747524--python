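en	cultivar	generation	flesh_color	mean	sd	n
1	DRD	Inbred	Scarlet red	589.45	71.88	5
2	SBA	Inbred	Coral red	225.84	45.06	5
3	SBB	Inbred	Coral red	164.04	28.53	5
4	45NC	Inbred	Coral red	213.47	28.25	5
5	DRDSBA	NIL (BC3F6)	Scarlet red	477.69	46.92	5
6	DRDSBB	NIL (BC3F9)	Scarlet red	369.60	44.79	5
7	DRD45NC	NIL (BC2F5)	Scarlet red	439.04	38.78	5
8	NS514	Inbred	Scarlet red	463.13	72.55	5
9	NS516	Inbred	Scarlet red	689.17	100.29	5
10	DRF5819	Inbred	Scarlet red	496.16	44.69	5
11	52192	Inbred	Coral red	213.16	64.66	5
12	Pink Variety	Inbred	Coral red	191.05	33.83	5
13	DRDSBA x SBA	Experimental F1	Coral red	193.43	25.46	5
14	DRDSBA x NS514	Experimental F1	Coral red	213.73	39.57	5
15	DRHS4105 x 52192	Experimental F1	Coral red	203.17	20.92	5
16	DRF5819 x 52192	Experimental F1	Coral red	142.64	14.76	5
17	SBA x 52192	Experimental F1	Coral red	189.62	46.04	5
18	Dangdanghan	Commercial F1	Coral red	135.77	18.07	5
19	Chamjoeun	Commercial F1	Coral red	189.79	29.12	5
20	Bigstart	Commercial F1	Coral red	211.99	35.02	5
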