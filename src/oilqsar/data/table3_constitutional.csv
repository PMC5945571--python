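id,nCs,nCt,nCconj,nRdCp,nRdCs,nRdCt,nRCO,nArOH,nOH,nHDon,nHAcc
1,0,0,1,0,0,0,0,0,0,0,2
2,3,1,0,0,0,0,1,0,0,0,1
3,2,2,0,0,1,1,0,0,0,0,0
4,0,1,0,0,0,0,0,1,0,1,1
5,3,1,0,1,1,2,0,0,1,1,1
6,4,3,0,0,0,0,0,0,1,1,1
7,2,1,3,1,1,2,1,0,0,0,1
8,3,2,0,0,1,1,0,0,1,1,1
9,4,2,0,1,1,2,0,0,0,0,0
10,3,1,0,0,1,1,0,0,0,0,1
11,3,1,0,0,1,1,0,0,1,1,1
12,0,0,0,0,0,0,0,1,0,1,1
13,0,0,0,0,0,0,0,1,0,1,1
14,0,1,1,0,0,0,0,0,0,0,1
15,0,1,0,0,0,0,0,0,0,0,0
16,3,2,0,1,0,1,1,0,0,0,1
17,0,1,0,0,0,0,0,0,0,0,0
18,4,1,0,0,0,0,0,0,0,0,0
19,2,0,3,0,2,2,0,0,0,0,1
20,2,0,0,0,2,2,0,0,1,1,1
21,4,2,4,1,3,2,0,0,0,0,0
22,4,0,0,0,4,2,0,0,0,0,0
23,2,2,3,0,1,1,1,0,1,1,2
24,3,3,0,0,0,0,1,0,1,1,2
25,0,1,0,0,0,0,0,1,0,1,1
26,4,1,0,0,0,0,0,0,1,1,1
27,4,2,0,1,0,1,0,0,1,1,1
28,3,3,0,0,0,0,1,0,0,0,1
29,2,1,0,1,1,2,0,0,1,1,1
30,3,1,0,1,1,2,0,0,0,0,0
31,2,1,0,1,2,1,0,0,1,1,1
32,4,3,0,0,0,0,0,0,0,1,1
33,3,3,0,0,0,0,1,0,0,0,1
34,2,0,4,2,2,2,0,0,0,0,0
35,4,2,0,1,0,1,0,0,1,1,1
36,3,1,3,1,1,2,0,0,0,0,1
37,2,1,4,0,2,2,0,0,0,0,0
38,2,2,0,0,1,1,0,0,0,0,0
39,3,2,0,1,0,1,0,0,0,0,0
40,3,1,3,0,0,2,1,0,0,0,1
41,3,1,3,0,0,2,1,0,0,0,2
42,3,2,0,1,0,1,0,0,0,0,0
43,2,1,4,0,2,2,0,0,0,0,0
44,2,1,0,0,2,2,0,0,0,0,0
45,3,2,0,0,1,1,0,0,1,1,1
46,3,2,0,0,1,1,0,0,1,1,1
47,4,2,0,1,0,1,0,0,1,1,1
48,4,1,0,0,0,2,0,0,1,1,1
49,3,0,0,0,1,3,0,0,0,0,0
50,0,1,0,0,0,0,0,1,0,1,1
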