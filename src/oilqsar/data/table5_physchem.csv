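id,Qpos,Qneg,Qtot,Ui,Hy,AMR,TPSA,MlogP,AlogP
1,1.28,-1.28,2.56,3.0,-0.768,39.112,26.3,1.49,1.573
2,1.659,-1.659,3.318,1.0,-0.877,44.492,17.07,2.357,1.936
3,1.413,-1.413,2.825,1.0,-0.96,44.722,0.0,3.374,2.873
4,1.5,-1.5,2.999,2.807,-0.294,46.984,20.23,2.813,3.243
5,1.234,-1.234,2.468,1.585,-0.294,47.995,20.23,2.25,2.401
6,1.249,-1.249,2.497,0.0,-0.294,47.445,20.23,2.502,2.779
7,1.665,-1.665,3.331,2.0,-0.877,47.174,17.07,2.153,2.361
8,1.704,-1.704,3.408,1.0,-0.294,48.218,20.23,2.357,2.597
9,1.926,-1.926,3.853,1.585,-0.975,62.851,0.0,4.375,4.297
10,1.288,-1.288,2.576,1.585,-0.877,49.297,17.07,2.642,3.019
11,1.791,-1.791,3.582,1.0,-0.294,50.486,20.23,2.749,3.049
12,0.884,-0.884,1.768,2.807,-0.158,32.793,20.23,1.859,2.049
13,0.867,-0.867,1.734,2.807,-0.158,32.793,20.23,1.859,2.049
14,1.444,-1.444,2.887,3.0,-0.877,46.84,17.07,2.723,2.784
15,1.315,-1.315,2.631,2.807,-0.96,45.29,0.0,3.562,3.51
16,1.283,-1.283,2.566,1.585,-0.877,46.298,17.07,2.25,2.401
17,0.905,-0.905,1.81,2.807,-0.965,50.331,0.0,3.854,3.997
18,1.422,-1.422,2.844,0.0,-0.96,43.799,0.0,4.431,3.077
19,1.283,-1.283,2.566,2.0,-0.877,50.199,17.07,2.545,3.19
20,1.684,-1.684,3.367,1.585,-0.294,51.182,20.23,2.642,2.934
21,1.478,-1.478,2.956,2.0,-0.977,70.55,0.0,4.534,5.135
22,1.446,-1.446,2.892,2.0,-0.977,71.549,0.0,4.534,5.035
23,1.596,-1.596,3.191,1.585,-0.244,49.154,37.3,1.369,1.274
24,1.612,-1.612,3.223,1.0,-0.244,48.278,37.3,1.477,1.313
25,1.06,-1.06,2.12,2.807,-0.257,41.943,20.23,2.51,2.757
26,1.157,-1.157,2.313,0.0,-0.294,45.314,20.23,2.502,1.975
27,1.232,-1.232,2.463,1.0,-0.294,47.222,20.23,2.357,2.583
28,1.286,-1.286,2.571,1.0,-0.877,46.52,17.07,2.357,2.597
29,1.344,-1.344,2.688,1.585,-0.325,54.812,20.23,2.933,3.105
30,1.438,-1.438,2.877,1.585,-0.96,46.48,0.0,3.267,3.503
31,1.882,-1.882,3.763,1.585,-0.294,50.206,20.23,2.642,2.735
32,1.772,-1.772,3.545,0.0,-0.294,47.445,20.23,2.502,2.779
33,1.288,-1.288,2.575,1.0,-0.877,46.52,17.07,2.357,2.597
34,1.526,-1.526,3.053,2.0,-0.96,48.379,0.0,3.562,3.688
35,1.27,-1.27,2.54,1.0,-0.294,47.222,20.23,2.357,2.583
36,1.231,-1.231,2.461,2.0,-0.877,47.272,17.07,2.153,2.668
37,0.89,-0.89,1.78,1.585,-0.96,47.553,0.0,3.267,3.449
38,1.398,-1.398,2.796,1.0,-0.96,44.722,0.0,3.374,2.873
39,0.933,-0.933,1.866,1.0,-0.96,43.65,0.0,3.374,2.927
40,1.224,-1.224,2.448,1.585,-0.877,47.129,17.07,2.25,2.752
41,1.236,-1.236,2.472,1.585,-0.807,46.637,29.6,1.369,1.824
42,1.47,-1.47,2.941,1.0,-0.96,43.65,0.0,3.374,2.927
43,1.386,-1.386,2.772,1.585,-0.96,47.553,0.0,3.267,3.449
44,0.892,-0.892,1.784,1.585,-0.96,47.553,0.0,3.267,3.449
45,1.257,-1.257,2.515,1.0,-0.294,48.307,20.23,2.357,2.55
46,1.247,-1.247,2.494,1.0,-0.294,48.461,20.23,2.357,2.415
47,1.288,-1.288,2.577,1.0,-0.294,47.388,20.23,2.357,2.469
48,1.195,-1.195,2.39,1.0,-0.294,48.194,20.23,2.357,2.61
49,1.369,-1.369,2.738,1.585,-0.96,47.286,0.0,3.267,3.643
50,1.523,-1.523,3.045,2.807,-0.294,46.984,20.23,2.813,3.243
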