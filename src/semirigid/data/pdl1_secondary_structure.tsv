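domain	res_start	res_end	kind	resid_start	resid_end
NtermA loop	1	9	loop	18	26
A strand	10	14	strand	27	31
AB loop	15	18	loop	32	35
B strand	19	24	strand	36	41
BH1 loop	25	31	loop	42	48
Helix1	32	35	helix	49	52
H1C loop	36	36	loop	53	53
C strand	37	42	strand	54	59
CC' loop	43	44	loop	60	61
C' strand	45	51	strand	62	68
C'C'' loop	52	53	loop	69	70
C'' strand	54	55	strand	71	72
C''H2 loop	56	56	loop	73	73
Helix2	57	65	helix	74	82
H2D loop	66	67	loop	83	84
D strand	68	70	strand	85	87
DH3 loop	71	71	loop	88	88
Helix3	72	77	helix	89	94
H3E loop	78	78	loop	95	95
E strand	79	84	strand	96	101
EH4 loop	85	87	loop	102	104
Helix4	88	92	helix	105	109
F strand	93	100	strand	110	117
FG loop	101	103	loop	118	120
G strand	104	114	strand	121	131
Grest loop	115	115	loop	132	132
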