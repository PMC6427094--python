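percentile,score
5,0.52
10,0.55
15,0.58
20,0.61
25,0.64
30,0.67
35,0.70
40,0.72
45,0.75
50,0.78
55,0.81
60,0.84
65,0.86
70,0.89
75,0.92
80,0.95
85,0.98
90,1.00
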