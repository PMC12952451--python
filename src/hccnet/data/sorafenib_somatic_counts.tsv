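#origin	somatic
#group	2	sensitive
#group	3	sensitive
#group	7	sensitive
#group	4	resistant
#group	5	resistant
#group	6	resistant
#group	8	resistant
#group	9	resistant
#group	10	resistant
#group	11	resistant
#group	12	resistant
#group	15	resistant
#group	16	resistant
gene	2	3	7	4	5	6	8	9	10	11	12	15	16
SLC15A2	0	0	0	0	0	0	0	0	0	0	0	0	1
RET	0	0	0	0	0	0	0	0	1	0	0	0	0
FLT1	0	0	0	0	0	0	0	0	1	0	0	0	0
NOS3	0	0	0	0	0	0	0	0	1	0	0	0	0
SLC22A1	0	0	0	0	0	0	0	0	1	0	0	0	0
ABCG2	0	0	0	0	1	0	0	0	0	0	0	0	1
FLT4	0	0	0	0	0	0	0	0	0	0	0	0	1
CYP3A4	0	0	0	0	0	0	0	0	0	0	0	0	1
CYP2C8	0	0	0	0	0	0	0	0	1	1	0	0	1
ABCC2	0	0	0	0	1	0	0	0	0	0	0	0	1
HIF1A	0	0	0	0	0	0	0	0	0	0	0	0	1
CYP2B6	0	0	0	0	0	0	0	0	1	0	0	0	1
MAPK12	0	0	0	0	0	0	0	0	0	0	0	0	1
RAF1	0	0	0	0	1	0	0	0	0	0	0	0	0
ABCB1	0	0	0	0	1	0	0	0	1	0	0	0	0
MAPK4	0	0	0	0	1	0	0	0	0	0	0	0	0
SLCO1B1	0	0	0	0	1	0	0	0	1	0	0	0	1
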