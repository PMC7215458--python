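n_deaths,n_accidents,F,lg_n,lg_f,slope
1,193,1.000,0,0,
2,91,0.480,0.301,-0.319,-1.060
3,28,0.235,0.477,-0.630,-1.320
4,21,0.159,0.602,-0.799,-1.326
5,8,0.102,0.699,-0.990,-1.416
6,4,0.078,0.778,-1.107,-1.423
7,5,0.067,0.845,-1.171,-1.386
8,3,0.054,0.903,-1.268,-1.404
9,3,0.046,0.954,-1.339,-1.403
11,1,0.038,1.041,-1.423,-1.367
12,4,0.035,1.079,-1.455,-1.349
15,1,0.024,1.176,-1.615,-1.373
17,1,0.022,1.230,-1.666,-1.354
20,1,0.019,1.301,-1.724,-1.325
29,2,0.016,1.462,-1.791,-1.225
36,1,0.011,1.556,-1.967,-1.264
40,1,0.008,1.602,-2.092,-1.306
41,1,0.005,1.613,-2.268,-1.406
58,1,0.003,1.763,-2.569,-1.457
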