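age,qx
60,0.00853
61,0.00930
62,0.01013
63,0.01104
64,0.01202
65,0.01310
66,0.01427
67,0.01554
68,0.01693
69,0.01844
70,0.02008
71,0.02187
72,0.02381
73,0.02593
74,0.02823
75,0.03073
76,0.03345
77,0.03640
78,0.03961
79,0.04310
80,0.04688
81,0.05099
82,0.05545
83,0.06029
84,0.06553
85,0.07121
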