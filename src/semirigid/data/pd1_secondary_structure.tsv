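domain	res_start	res_end	kind	resid_start	resid_end
NtermA' loop	116	126	loop	25	35
A' strand	127	129	strand	36	38
A'A loop	130	131	loop	39	40
A strand	132	136	strand	41	45
AB loop	137	140	loop	46	49
B strand	141	146	strand	50	55
BC loop	147	152	loop	56	61
C strand	153	161	strand	62	70
CC' loop	162	166	loop	71	75
C' strand	167	173	strand	76	82
C'D loop	174	185	loop	83	94
D strand	186	190	strand	95	99
DE loop	191	195	loop	100	104
E strand	196	201	strand	105	110
EF loop	202	209	loop	111	118
F strand	210	220	strand	119	129
FG loop	221	223	loop	130	132
G strand	224	227	strand	133	136
GG' loop	228	230	loop	137	139
G' strand	231	236	strand	140	145
G'rest loop	237	240	loop	146	149
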