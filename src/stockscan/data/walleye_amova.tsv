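analysis	stratum	df	ssq	variance
all	among_groups	1	39936.91	54.08
all	among_pops_within_groups	21	137207.96	67.26
all	within_pops	1655	2656558.49	1605.17
wisconsin	among_groups	4	33994.29	10.51
wisconsin	among_pops_within_groups	10	63073.48	55.18
wisconsin	within_pops	1241	2069472.47	1667.58
minnesota	among_groups	1	7049.11	7.05
minnesota	among_pops_within_groups	6	33091.07	78.32
minnesota	within_pops	414	587086.02	1418.08
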