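id,E_HOMO,E_LUMO,GAP,I,A,chi,mu,eta,sigma,dipole
1,-8.954,2.096,11.05,8.954,-2.096,-3.429,3.429,5.525,0.181,5.429
2,-10.343,3.969,14.312,10.343,-3.969,-3.187,3.187,7.156,0.14,3.927
3,-8.971,4.13,13.102,8.973,-4.13,-2.421,2.421,6.551,0.153,0.178
4,-8.351,4.112,12.463,8.351,-4.112,-2.119,2.119,6.232,0.16,1.672
5,-9.356,4.94,14.296,9.356,-4.94,-2.207,2.207,7.148,0.139,1.96
6,-10.751,6.545,17.296,10.751,-6.545,-2.102,2.102,8.648,0.115,1.751
7,-9.308,2.797,12.106,9.308,-2.797,-3.255,3.255,6.053,0.165,3.989
8,-8.945,5.27,14.215,8.945,-5.27,-1.837,1.837,7.108,0.14,1.864
9,-8.646,4.517,13.162,8.646,-4.517,-2.064,2.064,6.581,0.152,0.711
10,-9.08,4.409,13.49,9.08,-4.409,-2.335,2.335,6.745,0.148,2.873
11,-8.808,4.832,13.641,8.808,-4.832,-1.988,1.988,6.82,0.147,2.137
12,-8.545,3.951,12.496,8.545,-3.951,-2.297,2.297,6.248,0.16,1.368
13,-8.481,4.075,12.555,8.481,-4.075,-2.202,2.202,6.277,0.159,1.921
14,-9.18,1.997,11.177,9.18,-1.997,-3.591,3.591,5.588,0.179,4.237
15,-8.542,4.17,12.712,8.542,-4.17,-2.186,2.186,6.356,0.157,0.054
16,-9.491,3.82,13.311,9.491,-3.82,-2.835,2.835,6.656,0.15,3.599
17,-8.432,4.303,12.735,8.432,-4.303,-2.064,2.064,6.367,0.157,0.328
18,-10.288,5.493,15.782,10.288,-5.493,-2.397,2.397,7.891,0.127,1.727
19,-9.05,2.34,11.39,9.05,-2.346,-3.36,3.36,5.701,0.18,4.732
20,-8.859,4.724,13.583,8.859,-4.724,-2.068,2.068,6.792,0.147,2.409
21,-8.268,4.476,12.744,8.268,-4.476,-1.896,1.896,6.372,0.157,0.39
22,-8.704,4.909,13.613,8.704,-4.909,-1.897,1.897,6.807,0.147,0.206
23,-7.752,6.518,14.271,7.753,-6.518,-0.617,0.617,7.136,0.14,3.777
24,-10.387,4.417,14.804,10.387,-4.417,-2.985,2.985,7.402,0.135,2.525
25,-8.523,3.985,12.508,8.523,-3.985,-2.268,2.268,6.254,0.159,1.397
26,-10.727,5.844,16.571,10.727,-5.844,-2.441,2.441,8.286,0.121,1.855
27,-9.46,5.094,14.554,9.461,-5.094,-2.183,2.183,7.278,0.137,3.754
28,-10.473,3.961,14.434,10.474,-3.961,-3.256,3.256,7.217,0.138,3.506
29,-8.98,3.88,12.86,8.98,-3.88,-2.55,2.55,6.43,0.16,2.32
30,-8.745,4.901,13.646,8.746,-4.901,-1.922,1.922,6.824,0.146,0.586
31,-9.082,4.442,13.524,9.082,-4.442,-2.32,2.32,6.762,0.148,1.361
32,-10.918,5.517,16.435,10.918,-5.517,2.7,-2.7,8.218,0.121,2.047
33,-10.711,3.419,14.13,10.712,-3.419,-3.645,3.645,7.066,0.141,3.632
34,-8.519,5.024,13.542,8.519,-5.024,-1.747,1.747,6.771,0.148,0.751
35,-9.605,4.832,14.437,9.605,-4.832,-2.386,2.386,7.219,0.138,2.324
36,-9.442,2.596,12.038,9.442,-2.596,-3.422,3.422,6.019,0.166,3.631
37,-7.764,3.901,11.674,7.764,-3.901,-1.926,1.926,5.837,0.171,0.516
38,-8.695,5.17,13.865,8.695,-5.17,-1.763,1.763,6.933,0.144,0.176
39,-8.695,5.17,13.865,8.695,-5.17,-1.763,1.763,6.933,0.144,0.164
40,-9.146,3.51,12.656,9.146,-3.51,-2.818,2.818,6.328,0.158,3.559
41,-9.391,2.798,12.189,9.392,-2.798,-3.296,3.296,6.095,0.164,3.748
42,-8.885,4.062,12.947,8.885,-4.062,-2.411,2.411,6.474,0.154,0.841
43,-9.001,3.052,12.053,9.001,-3.052,-2.975,2.975,6.027,0.165,0.802
44,-7.64,3.378,11.018,7.641,-3.378,-2.131,2.131,5.509,0.181,0.648
45,-9.355,5.102,14.457,9.355,-5.102,-2.126,2.126,7.229,0.138,1.841
46,-9.016,3.878,12.895,9.016,-3.878,-2.569,2.569,6.447,0.155,1.901
47,-9.892,3.097,12.989,9.892,-3.097,-3.397,3.397,6.495,0.153,1.691
48,-9.371,3.852,13.222,9.371,-3.852,-2.759,2.759,6.611,0.151,1.772
49,-8.475,4.996,13.471,8.475,-4.996,-1.739,1.739,6.735,0.148,0.198
50,-8.325,4.145,12.47,8.325,-4.145,-2.09,2.09,6.235,0.161,1.765
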