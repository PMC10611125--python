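patient,accuracy,specificity,sensitivity,auc,f1
1,0.95,0.95,0.95,0.99,0.89
2,0.97,0.97,0.91,0.98,0.83
3,0.92,0.92,0.9,0.95,0.81
4,0.93,0.93,0.81,0.93,0.71
5,0.89,0.89,0.94,0.97,0.83
6,0.92,0.92,0.31,0.74,0.19
7,0.98,0.98,0.87,0.98,0.81
8,0.88,0.88,0.74,0.89,0.71
9,0.98,0.98,0.95,0.98,0.87
10,0.95,0.95,0.94,0.97,0.87
11,0.95,0.95,0.91,0.98,0.89
12,0.94,0.94,0.83,0.95,0.82
13,0.54,0.55,0.41,0.46,0.35
14,0.97,0.97,0.73,0.95,0.68
15,0.91,0.91,0.34,0.81,0.33
16,0.95,0.95,0.53,0.9,0.41
17,0.85,0.85,0.83,0.93,0.72
18,0.96,0.96,0.87,0.96,0.81
19,0.98,0.98,0.88,0.98,0.84
20,0.93,0.93,0.57,0.79,0.51
21,0.94,0.94,0.84,0.96,0.73
22,0.94,0.94,1,0.99,0.875
23,0.93,0.93,0.91,0.97,0.85
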