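#origin	germline
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
BARD1	0	0	0	0	1	0	0	0	0	1	0	0	0
SDHC	0	0	0	0	0	0	0	0	0	0	1	0	0
NF1	0	0	0	0	0	0	1	0	0	0	1	0	0
MLH1	0	0	0	0	0	0	0	0	0	0	0	1	0
MET	0	0	0	0	1	0	0	0	0	0	0	1	0
XPC	0	0	0	1	0	0	0	0	0	0	0	0	1
FANCC	0	0	0	0	0	0	0	0	0	0	0	0	1
SDHAF2	0	0	0	0	0	0	1	0	0	0	0	0	0
CDH1	0	0	0	0	0	0	1	0	0	0	0	0	0
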