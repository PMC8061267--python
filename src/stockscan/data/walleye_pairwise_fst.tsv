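pop_i	pop_j	fst
2	1	0.039
3	1	0.041
3	2	0.019
4	1	0.064
4	2	0.054
4	3	0.037
5	1	0.025
5	2	0.016
5	3	0.016
5	4	0.029
6	1	0.037
6	2	0.03
6	3	0.024
6	4	0.025
6	5	0.005
7	1	0.037
7	2	0.033
7	3	0.024
7	4	0.025
7	5	0.009
7	6	0.0
8	1	0.042
8	2	0.04
8	3	0.029
8	4	0.033
8	5	0.016
8	6	0.01
8	7	0.009
9	1	0.074
9	2	0.075
9	3	0.064
9	4	0.067
9	5	0.047
9	6	0.045
9	7	0.044
9	8	0.055
10	1	0.042
10	2	0.035
10	3	0.023
10	4	0.019
10	5	0.01
10	6	0.0
10	7	0.003
10	8	0.009
10	9	0.047
11	1	0.038
11	2	0.027
11	3	0.017
11	4	0.024
11	5	0.009
11	6	0.003
11	7	0.005
11	8	0.008
11	9	0.05
11	10	0.003
12	1	0.037
12	2	0.033
12	3	0.02
12	4	0.031
12	5	0.016
12	6	0.009
12	7	0.011
12	8	0.008
12	9	0.057
12	10	0.009
12	11	0.004
13	1	0.071
13	2	0.075
13	3	0.059
13	4	0.079
13	5	0.064
13	6	0.063
13	7	0.061
13	8	0.049
13	9	0.105
13	10	0.062
13	11	0.04
13	12	0.035
14	1	0.047
14	2	0.047
14	3	0.03
14	4	0.038
14	5	0.019
14	6	0.005
14	7	0.009
14	8	0.008
14	9	0.059
14	10	0.009
14	11	0.007
14	12	0.006
14	13	0.046
15	1	0.065
15	2	0.051
15	3	0.041
15	4	0.071
15	5	0.047
15	6	0.053
15	7	0.053
15	8	0.056
15	9	0.096
15	10	0.054
15	11	0.047
15	12	0.045
15	13	0.082
15	14	0.059
16	1	0.112
16	2	0.112
16	3	0.091
16	4	0.111
16	5	0.095
16	6	0.094
16	7	0.094
16	8	0.093
16	9	0.14
16	10	0.096
16	11	0.089
16	12	0.082
16	13	0.115
16	14	0.098
16	15	0.07
17	1	0.06
17	2	0.054
17	3	0.037
17	4	0.061
17	5	0.043
17	6	0.044
17	7	0.044
17	8	0.042
17	9	0.089
17	10	0.044
17	11	0.036
17	12	0.03
17	13	0.063
17	14	0.044
17	15	0.043
17	16	0.053
18	1	0.055
18	2	0.061
18	3	0.036
18	4	0.055
18	5	0.039
18	6	0.035
18	7	0.036
18	8	0.035
18	9	0.084
18	10	0.037
18	11	0.032
18	12	0.025
18	13	0.057
18	14	0.043
18	15	0.048
18	16	0.068
18	17	0.025
19	1	0.094
19	2	0.098
19	3	0.076
19	4	0.096
19	5	0.078
19	6	0.077
19	7	0.077
19	8	0.076
19	9	0.122
19	10	0.078
19	11	0.073
19	12	0.066
19	13	0.098
19	14	0.083
19	15	0.082
19	16	0.097
19	17	0.06
19	18	0.05
20	1	0.08
20	2	0.08
20	3	0.061
20	4	0.081
20	5	0.064
20	6	0.064
20	7	0.062
20	8	0.06
20	9	0.109
20	10	0.064
20	11	0.057
20	12	0.049
20	13	0.082
20	14	0.064
20	15	0.058
20	16	0.062
20	17	0.038
20	18	0.024
20	19	0.057
21	1	0.081
21	2	0.087
21	3	0.061
21	4	0.083
21	5	0.065
21	6	0.064
21	7	0.064
21	8	0.063
21	9	0.111
21	10	0.066
21	11	0.061
21	12	0.052
21	13	0.085
21	14	0.072
21	15	0.054
21	16	0.049
21	17	0.039
21	18	0.042
21	19	0.07
21	20	0.032
22	1	0.067
22	2	0.069
22	3	0.049
22	4	0.069
22	5	0.051
22	6	0.05
22	7	0.05
22	8	0.048
22	9	0.096
22	10	0.05
22	11	0.044
22	12	0.037
22	13	0.07
22	14	0.052
22	15	0.053
22	16	0.065
22	17	0.03
22	18	0.019
22	19	0.053
22	20	0.021
22	21	0.03
23	1	0.103
23	2	0.104
23	3	0.084
23	4	0.105
23	5	0.088
23	6	0.088
23	7	0.088
23	8	0.087
23	9	0.133
23	10	0.089
23	11	0.083
23	12	0.076
23	13	0.108
23	14	0.093
23	15	0.076
23	16	0.068
23	17	0.064
23	18	0.068
23	19	0.097
23	20	0.071
23	21	0.055
23	22	0.064
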