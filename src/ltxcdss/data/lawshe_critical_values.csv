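n_experts,critical_cvr
5,0.99
6,0.99
7,0.99
8,0.75
9,0.78
10,0.62
11,0.59
12,0.56
13,0.54
14,0.51
15,0.49
20,0.42
25,0.37
30,0.33
35,0.31
40,0.29
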