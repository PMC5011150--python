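# source: digitized correlation of PoreWalker cavity-lining residues
# with MEMSAT-SVM pore-lining residues; Met-inclusive numbering.
protein_id	cavity_position	pore_position
CYGB	125	125
CYGB	126	126
CYGB		127
CYGB	128	128
CYGB	129	129
CYGB	130	130
CYGB	131	131
CYGB	132	132
CYGB	133	133
CYGB	134	134
CYGB	135	135
CYGB		136
CYGB		137
CYGB		138
CYGB		139
CYGB		140
HBB	105	
HBB		106
HBB		107
HBB	108	108
HBB	109	109
HBB		110
HBB		111
HBB	112	112
HBB	113	113
HBB		114
HBB	115	115
HBB	116	116
HBB	117	117
HBB		118
HBB		119
HBB		120
MB	104	105
MB		106
MB		107
MB	107	108
MB	108	109
MB		110
MB	110	111
MB	111	112
MB		113
MB		114
MB	114	115
MB	115	116
MB		117
MB	118	118
MB	119	119
MB	120	120
NGB	133	133
NGB		134
NGB		135
NGB	136	136
NGB	137	137
NGB	139	138
NGB	140	139
NGB	141	140
NGB	142	141
NGB		142
NGB	144	143
NGB		144
NGB	146	145
NGB		146
NGB		147
NGB		148
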