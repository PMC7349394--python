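site_id,n,h,Hd,Pi
1,20,5,0.442,0.00074
2,20,5,0.442,0.00120
3,20,3,0.353,0.00178
4,20,7,0.521,0.01813
5,20,4,0.363,0.00105
6,20,4,0.284,0.00091
7,20,3,0.353,0.00178
8,20,4,0.363,0.00105
9,20,5,0.368,0.00106
10,9,4,0.583,0.00203
11,20,6,0.516,0.00186
12,10,3,0.378,0.00061
15,20,6,0.447,0.00122
16,20,2,0.100,0.00015
17,3,2,0.667,0.00101
18,20,5,0.511,0.00174
19,20,3,0.195,0.00030
20,20,3,0.353,0.00178
21,20,2,0.100,0.00015
22,20,4,0.284,0.00046
23,20,4,0.284,0.00046
24,20,6,0.516,0.00219
25,20,6,0.574,0.00259
26,20,2,0.100,0.00015
29,8,2,0.250,0.00152
30,20,6,0.516,0.00090
31,20,4,0.284,0.00091
32,20,5,0.626,0.00278
33,20,3,0.353,0.00102
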