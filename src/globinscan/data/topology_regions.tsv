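# source: published MEMSAT-SVM pore-lining regions and TM helices
# with their published endpoint residue letters.  The publication
# mixes Met-inclusive and mature numbering between columns; endpoint
# letters are kept verbatim so validate_endpoints can diagnose the
# offset per row.
protein_id	label	start	end	start_res	end_res
BAND3	PORE_LINING	740	770	V	P
BAND3	PORE_LINING	827	885	F	K
BAND3	PORE_LINING	928	950	G	Y
BAND3	PORE_LINING	1027	1048	D	A
BAND3	PORE_LINING	1107	1122	L	L
CYGB	PORE_LINING	125	140	K	A
HBA	TM_HELIX	106	121	I	K
HBB	PORE_LINING	105	121	L	K
MB	PORE_LINING	105	120	L	H
NGB	PORE_LINING	133	148	W	W
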