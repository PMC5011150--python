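# source: digitized PoreWalker cavity-lining residue lists for the
# globin crystal structures 1UMO (CYGB), 1OJ6 (NGB), 3RGK (MB) and
# 1GZX beta chain (HBB); Met-inclusive numbering.  The MB column of
# the available source text preserves 53 of the 55 stated residues
# (two cells lost in text extraction); CYGB digitizes to 56 against
# stated counts of 43/57 (the source contradicts itself).
protein_id	position
CYGB	18
CYGB	19
CYGB	20
CYGB	23
CYGB	24
CYGB	27
CYGB	28
CYGB	30
CYGB	31
CYGB	34
CYGB	37
CYGB	38
CYGB	48
CYGB	49
CYGB	52
CYGB	53
CYGB	54
CYGB	55
CYGB	67
CYGB	84
CYGB	86
CYGB	89
CYGB	92
CYGB	93
CYGB	96
CYGB	99
CYGB	102
CYGB	106
CYGB	109
CYGB	111
CYGB	113
CYGB	122
CYGB	124
CYGB	125
CYGB	126
CYGB	128
CYGB	129
CYGB	130
CYGB	131
CYGB	132
CYGB	133
CYGB	134
CYGB	135
CYGB	143
CYGB	148
CYGB	150
CYGB	151
CYGB	152
CYGB	153
CYGB	154
CYGB	155
CYGB	157
CYGB	158
CYGB	159
CYGB	161
CYGB	162
HBB	15
HBB	19
HBB	22
HBB	25
HBB	26
HBB	27
HBB	30
HBB	31
HBB	33
HBB	34
HBB	35
HBB	37
HBB	52
HBB	55
HBB	61
HBB	64
HBB	68
HBB	77
HBB	101
HBB	102
HBB	104
HBB	105
HBB	108
HBB	109
HBB	112
HBB	113
HBB	115
HBB	116
HBB	117
HBB	131
HBB	132
HBB	134
HBB	135
HBB	139
HBB	143
MB	9
MB	12
MB	13
MB	14
MB	16
MB	17
MB	20
MB	21
MB	24
MB	25
MB	27
MB	28
MB	29
MB	31
MB	32
MB	43
MB	64
MB	65
MB	66
MB	68
MB	69
MB	72
MB	75
MB	76
MB	85
MB	86
MB	89
MB	93
MB	99
MB	100
MB	101
MB	103
MB	104
MB	107
MB	108
MB	110
MB	111
MB	114
MB	115
MB	118
MB	119
MB	120
MB	122
MB	123
MB	131
MB	132
MB	134
MB	135
MB	138
MB	139
MB	142
MB	143
MB	146
NGB	3
NGB	67
NGB	68
NGB	71
NGB	72
NGB	73
NGB	74
NGB	75
NGB	78
NGB	79
NGB	81
NGB	82
NGB	83
NGB	84
NGB	85
NGB	86
NGB	87
NGB	88
NGB	89
NGB	90
NGB	91
NGB	92
NGB	94
NGB	95
NGB	96
NGB	104
NGB	105
NGB	109
NGB	114
NGB	133
NGB	136
NGB	137
NGB	139
NGB	140
NGB	141
NGB	142
NGB	144
NGB	146
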