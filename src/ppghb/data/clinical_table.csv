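id,hemoglobin_g_per_L,gender,age,systolic_mmHg,diastolic_mmHg,heart_rate_bpm,creatinine_umol_per_L,urea_mmol_per_L
1,135,male,23,,,,,
2,128,female,25,,,,,
3,130,male,72,129,80,70,94.8,8.09
4,136,male,21,,,,,
5,110,male,48,147,97,79,67.3,2.91
6,148.5,male,26,,,,,
7,147.9,male,36,,,,,
8,119,female,30,165,107,70,173.8,8.92
9,136.5,male,25,,,,,
10,117,male,36,129,102,93,229.8,10.34
11,133,male,24,,,,,
12,118,male,38,160,98,75,360.2,27.17
13,92,male,38,,,,,
14,125,female,28,,,,,
15,133,female,64,120,76,85,66.3,5.38
16,124,female,55,155,84,63,61.1,5.16
17,106,male,58,141,93,63,551.3,29.5
18,119,male,24,,,,,
19,131,male,26,,,,,
20,124,female,25,120,80,86,90,4
21,150,male,28,,,,,
22,88,male,27,152,92,84,207.1,13.07
23,102.5,male,48,,,,,
24,126,female,26,,,,,
25,133,female,24,,,,,
26,115,male,40,,,,,
27,140,female,41,,,,,
28,129.7,female,30,,,,,
29,132.7,male,24,,,,,
30,103,female,33,,,,,
31,109,male,30,,,,,
32,132,female,24,,,,,
33,122,male,36,,,,,
34,123,female,39,,,,,
35,134.6,male,25,,,,,
36,132,male,26,,,,,
37,118,male,35,,,,,
38,138,female,,,,,,
39,127,male,26,,,,,
40,132,female,23,,,,,
41,128,female,39,117,63,70,67.3,2.91
42,129,female,25,,,,,
43,128,female,27,,,,,
44,138,male,24,110,80,70,90,4
45,136,male,27,155,110,60,178.4,9.04
46,133,male,20,160,101,97,344.1,34.16
47,136,male,36,,,,,
48,135,male,24,110,80,88,90,4
49,125,female,28,,,,,
50,125,female,,,,,,
51,134,male,44,,,,,
52,127.9,female,55,125,74,68,,
53,127,female,36,,,,,
54,131,male,24,,,,,
55,129,female,25,,,,,
56,96,male,32,152,92,86,474.6,4.29
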