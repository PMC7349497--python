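trial,actual_g,recall_24hr_g,myfitnesspal_g,scanner_g
1,19,34,78,30
2,100,42,52,122
3,30,39,NF,80
4,121,46,NF,94
5,18,59,NF,25
6,61,58,156,62
7,46,49,68,39
8,78,75,56,39
9,61,44,NF,28
10,86,24,17,104
11,14,129,NF,7
12,58,26,50,35
13,84,13,17,94
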