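id,J,TIE,UNIP,CENT,VAR,BAC,Lop,ICR,CSI,ECC,PHI
1,2.174,10.042,21,40,14,9,1.261,1.922,100,52,2.185
2,2.396,18.594,16,70,13,17,0.845,1.322,73,36,1.135
3,2.037,10.135,17,46,12,10,0.853,1.571,84,40,1.073
4,2.396,14.877,21,73,14,18,1.16,1.868,99,52,2.3
5,2.396,18.074,21,73,14,18,1.16,1.868,99,52,2.504
6,2.396,19.928,21,73,14,18,1.16,1.868,99,52,2.941
7,2.396,18.471,21,73,14,18,1.16,1.868,99,52,2.281
8,2.396,18.314,21,73,14,18,1.16,1.868,99,52,2.717
9,2.059,19.097,29,144,20,17,0.788,1.531,148,72,2.328
10,3.1,25.28,26,102,22,29,2.187,2.231,122,70,5.82
11,3.1,24.613,26,102,22,29,2.187,2.231,122,70,6.24
12,2.231,6.729,13,18,6,5,0.875,1.0,54,28,1.31
13,2.279,7.081,12,24,6,5,0.875,1.0,54,28,1.31
14,2.243,13.72,23,71,19,14,1.273,1.936,113,59,2.425
15,2.26,9.324,18,60,14,11,1.185,1.971,88,46,2.103
16,2.396,20.345,21,73,14,18,1.16,1.868,99,52,2.483
17,2.396,11.627,21,73,14,18,1.16,1.868,99,52,2.33
18,2.369,11.204,14,48,8,10,0.853,0.722,58,28,1.068
19,3.1,21.175,26,102,22,29,2.187,2.231,122,70,5.452
20,3.1,20.675,26,102,22,29,2.187,2.231,122,70,5.858
21,2.45,24.92,38,158,22,18,1.029,1.506,171,88,4.873
22,2.453,23.917,41,103,18,17,0.769,0.918,166,85,4.379
23,2.512,28.931,23,102,18,27,1.124,1.855,110,58,2.383
24,2.512,31.085,23,102,18,27,1.124,1.855,110,58,2.573
25,2.32,11.61,17,64,12,11,1.185,1.522,80,42,2.073
26,2.396,17.859,16,70,13,17,0.845,1.322,73,36,1.258
27,2.437,20.001,20,80,16,18,1.16,1.936,95,50,2.717
28,2.437,20.893,20,80,16,18,1.16,1.936,95,50,2.695
29,3.631,30.981,25,146,24,42,1.888,1.959,118,68,5.733
30,2.26,11.025,18,60,14,11,1.185,1.971,88,46,2.311
31,3.376,29.883,24,96,18,37,1.859,1.936,109,63,4.126
32,2.437,20.222,20,80,16,18,1.16,1.936,95,50,2.941
33,2.437,20.893,20,80,16,18,1.16,1.936,95,50,2.695
34,3.033,15.472,22,72,16,28,1.922,1.971,98,57,4.649
35,2.437,20.001,20,80,16,18,1.16,1.936,95,50,2.717
36,2.243,16.093,23,71,19,14,1.273,1.936,113,59,2.641
37,2.26,10.108,18,60,14,11,1.185,1.971,88,46,2.311
38,2.156,10.238,16,44,10,10,0.853,1.0,74,35,1.073
39,2.156,10.914,16,44,10,10,0.853,1.0,74,35,1.073
40,2.437,18.381,20,80,16,18,1.16,1.936,95,50,2.483
41,2.044,19.068,23,86,16,18,1.126,1.959,114,55,1.464
42,2.106,10.81,15,64,13,11,1.185,1.571,80,39,1.073
43,2.26,10.108,18,60,14,11,1.185,1.971,88,46,2.311
44,2.26,9.965,18,60,14,11,1.185,1.971,88,46,2.311
45,2.481,20.27,19,87,18,18,1.16,1.981,97,51,2.382
46,2.394,19.231,20,84,18,18,1.16,1.936,99,52,2.382
47,2.362,20.311,22,66,14,18,1.16,1.936,99,52,2.382
48,2.362,18.58,22,66,14,18,1.16,1.936,99,52,2.382
49,2.26,9.616,18,60,14,11,1.185,1.971,88,46,2.311
50,2.437,15.124,20,80,16,18,1.16,1.936,95,50,2.3
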