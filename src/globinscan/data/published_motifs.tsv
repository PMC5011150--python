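# source: published inventory of CRAC/CARC and caveolin-binding
# motif spans.  verifiable=0 rows have internally inconsistent
# printed coordinates or endpoint letters (see note column); they
# are excluded from exact span assertions.
protein_id	category	start	end	start_res	end_res	verifiable	note
CYGB	cholesterol	33	41	R	V	1	
CYGB	cholesterol	119	125	V	K	1	
CYGB	cholesterol	155	162	R	V	1	
NGB	cholesterol	30	34	R	L	1	
NGB	cholesterol	38	37	L	R	0	printed end 37 < start 38; scanner span 38-47
NGB	cholesterol	85	94	L	R	1	
NGB	cholesterol	152	109	K	V	0	printed start 152 exceeds length 151; scanner span 102-109
NGB	cholesterol	113	119	L	K	1	
NGB	caveolin	42	49	F	F	1	
MB	cholesterol	43	50	K	L	1	
MB	cholesterol	140	150	K	L	0	Met-offset: scanner span 141-150 under Met-inclusive numbering
HBA	cholesterol	41	49	K	L	1	
HBA	cholesterol	92	100	R	K	0	endpoint letters fit neither grammar; scanner span 93-102
HBB	cholesterol	41	49	R	L	1	
HBB	cholesterol	66	76	K	L	1	
HBB	cholesterol	83	92	K	L	1	
HBB	cholesterol	121	127	K	V	1	
HBB	cholesterol	127	133	V	K	1	
HBB	caveolin	36	43	Y	F	1	8-mer span; the full caveolin domain is 36-46
BAND3	cholesterol	316	324	K	L	1	
BAND3	cholesterol	623	633	R	L	1	
BAND3	cholesterol	692	700	Y	L	0	printed start letter Y fits neither grammar; surrogate plants a CARC here
BAND3	cholesterol	789	793	Y	R	0	printed start letter Y fits neither grammar; surrogate plants a CRAC here
BAND3	cholesterol	833	842	L	K	1	
BAND3	cholesterol	967	975	K	L	1	
BAND3	cholesterol	979	986	R	V	1	
BAND3	cholesterol	1020	1030	K	L	1	
BAND3	cholesterol	1154	1163	R	L	1	
BAND3	cholesterol	1198	1205	R	L	1	
BAND3	caveolin	66	73	Y	F	1	
BAND3	caveolin	774	781	F	F	1	
BAND3	caveolin	822	829	F	F	1	
BAND3	caveolin	955	913	F	F	0	printed end 913 < start 955; surrogate plants an 8-mer at 955-962
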