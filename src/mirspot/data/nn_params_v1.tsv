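# mirspot nearest-neighbor duplex parameter table
# columns: kind<TAB>key1<TAB>key2<TAB>value
# stack keys are (guide base + target base) pairs, 5'-side pair first
version	v1		
init			4.09
terminal_au_gu			0.45
max_loop_side			40
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	AU	GC	-2.08
stack	AU	CG	-2.24
stack	AU	GU	-0.94
stack	AU	UG	-0.50
stack	UA	AU	-1.33
stack	UA	UA	-0.93
stack	UA	GC	-2.11
stack	UA	CG	-2.35
stack	UA	GU	-0.95
stack	UA	UG	-0.42
stack	GC	AU	-2.35
stack	GC	UA	-2.24
stack	GC	GC	-3.26
stack	GC	CG	-3.42
stack	GC	GU	-1.47
stack	GC	UG	-1.01
stack	CG	AU	-2.11
stack	CG	UA	-2.08
stack	CG	GC	-2.36
stack	CG	CG	-3.26
stack	CG	GU	-1.06
stack	CG	UG	-0.94
stack	GU	AU	-1.06
stack	GU	UA	-1.01
stack	GU	GC	-1.47
stack	GU	CG	-1.50
stack	GU	GU	-0.80
stack	GU	UG	-0.56
stack	UG	AU	-0.60
stack	UG	UA	-0.42
stack	UG	GC	-0.95
stack	UG	CG	-1.06
stack	UG	GU	-0.53
stack	UG	UG	-0.23
bulge	1		3.20
bulge	2		3.80
bulge	3		4.40
bulge	4		5.00
bulge	5		5.60
bulge	6		6.20
bulge	7		6.80
bulge	8		7.40
bulge	9		8.00
bulge	10		8.60
bulge	11		9.20
bulge	12		9.80
bulge	13		10.40
bulge	14		11.00
bulge	15		11.60
bulge	16		12.20
bulge	17		12.80
bulge	18		13.40
bulge	19		14.00
bulge	20		14.60
bulge	21		15.20
bulge	22		15.80
bulge	23		16.40
bulge	24		17.00
bulge	25		17.60
bulge	26		18.20
bulge	27		18.80
bulge	28		19.40
bulge	29		20.00
bulge	30		20.60
bulge	31		21.20
bulge	32		21.80
bulge	33		22.40
bulge	34		23.00
bulge	35		23.60
bulge	36		24.20
bulge	37		24.80
bulge	38		25.40
bulge	39		26.00
bulge	40		26.60
interior	2		1.70
interior	3		2.20
interior	4		2.70
interior	5		3.20
interior	6		3.70
interior	7		4.20
interior	8		4.70
interior	9		5.20
interior	10		5.70
interior	11		6.20
interior	12		6.70
interior	13		7.20
interior	14		7.70
interior	15		8.20
interior	16		8.70
interior	17		9.20
interior	18		9.70
interior	19		10.20
interior	20		10.70
interior	21		11.20
interior	22		11.70
interior	23		12.20
interior	24		12.70
interior	25		13.20
interior	26		13.70
interior	27		14.20
interior	28		14.70
interior	29		15.20
interior	30		15.70
interior	31		16.20
interior	32		16.70
interior	33		17.20
interior	34		17.70
interior	35		18.20
interior	36		18.70
interior	37		19.20
interior	38		19.70
interior	39		20.20
interior	40		20.70
interior	41		21.20
interior	42		21.70
interior	43		22.20
interior	44		22.70
interior	45		23.20
interior	46		23.70
interior	47		24.20
interior	48		24.70
interior	49		25.20
interior	50		25.70
interior	51		26.20
interior	52		26.70
interior	53		27.20
interior	54		27.70
interior	55		28.20
interior	56		28.70
interior	57		29.20
interior	58		29.70
interior	59		30.20
interior	60		30.70
interior	61		31.20
interior	62		31.70
interior	63		32.20
interior	64		32.70
interior	65		33.20
interior	66		33.70
interior	67		34.20
interior	68		34.70
interior	69		35.20
interior	70		35.70
interior	71		36.20
interior	72		36.70
interior	73		37.20
interior	74		37.70
interior	75		38.20
interior	76		38.70
interior	77		39.20
interior	78		39.70
interior	79		40.20
interior	80		40.70
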