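# material: concrete
# density_g_cm3: 2.3
# composition: H:0.022100,C:0.002484,O:0.574930,Na:0.015208,Mg:0.001266,Al:0.019953,Si:0.304627,K:0.010045,Ca:0.042951,Fe:0.006435
# columns: energy_kev photoelectric_cm2_g incoherent_cm2_g coherent_cm2_g
10.0	2.419943e+01	1.964476e-01	6.690809e-02
11.0	1.798040e+01	1.957280e-01	5.882978e-02
12.0	1.370965e+01	1.950153e-01	5.230961e-02
13.0	1.068282e+01	1.943095e-01	4.695172e-02
14.0	8.479651e+00	1.936103e-01	4.248163e-02
15.0	6.839017e+00	1.929178e-01	3.870346e-02
16.0	5.592919e+00	1.922319e-01	3.547400e-02
17.0	4.630000e+00	1.915523e-01	3.268626e-02
18.0	3.874494e+00	1.908791e-01	3.025886e-02
19.0	3.273657e+00	1.902122e-01	2.812888e-02
20.0	2.790010e+00	1.895515e-01	2.624693e-02
21.0	2.396440e+00	1.888968e-01	2.457380e-02
22.0	2.073004e+00	1.882482e-01	2.307794e-02
23.0	1.804817e+00	1.876054e-01	2.173374e-02
24.0	1.580619e+00	1.869686e-01	2.052019e-02
25.0	1.391788e+00	1.863375e-01	1.941990e-02
26.0	1.231648e+00	1.857120e-01	1.841838e-02
27.0	1.094974e+00	1.850922e-01	1.750346e-02
28.0	9.776395e-01	1.844780e-01	1.666484e-02
29.0	8.763577e-01	1.838692e-01	1.589376e-02
30.0	7.884869e-01	1.832657e-01	1.518272e-02
31.0	7.118890e-01	1.826676e-01	1.452528e-02
32.0	6.448212e-01	1.820748e-01	1.391586e-02
33.0	5.858531e-01	1.814871e-01	1.334960e-02
34.0	5.338039e-01	1.809046e-01	1.282228e-02
35.0	4.876925e-01	1.803271e-01	1.233018e-02
36.0	4.466998e-01	1.797545e-01	1.187005e-02
37.0	4.101383e-01	1.791869e-01	1.143900e-02
38.0	3.774278e-01	1.786241e-01	1.103449e-02
39.0	3.480769e-01	1.780662e-01	1.065424e-02
40.0	3.216671e-01	1.775129e-01	1.029623e-02
41.0	2.978409e-01	1.769643e-01	9.958659e-03
42.0	2.762914e-01	1.764204e-01	9.639892e-03
43.0	2.567545e-01	1.758809e-01	9.338476e-03
44.0	2.390017e-01	1.753460e-01	9.053093e-03
45.0	2.228348e-01	1.748155e-01	8.782555e-03
46.0	2.080817e-01	1.742894e-01	8.525785e-03
47.0	1.945918e-01	1.737676e-01	8.281806e-03
48.0	1.822334e-01	1.732501e-01	8.049728e-03
49.0	1.708909e-01	1.727368e-01	7.828740e-03
50.0	1.604626e-01	1.722277e-01	7.618102e-03
51.0	1.508587e-01	1.717227e-01	7.417137e-03
52.0	1.419997e-01	1.712217e-01	7.225223e-03
53.0	1.338150e-01	1.707248e-01	7.041790e-03
54.0	1.262422e-01	1.702318e-01	6.866314e-03
55.0	1.192252e-01	1.697428e-01	6.698312e-03
56.0	1.127144e-01	1.692576e-01	6.537337e-03
57.0	1.066651e-01	1.687763e-01	6.382979e-03
58.0	1.010374e-01	1.682987e-01	6.234856e-03
59.0	9.579531e-02	1.678249e-01	6.092616e-03
60.0	9.090656e-02	1.673547e-01	5.955930e-03
61.0	8.634203e-02	1.668882e-01	5.824495e-03
62.0	8.207541e-02	1.664253e-01	5.698027e-03
63.0	7.808291e-02	1.659660e-01	5.576264e-03
64.0	7.434300e-02	1.655102e-01	5.458960e-03
65.0	7.083609e-02	1.650578e-01	5.345885e-03
66.0	6.754443e-02	1.646089e-01	5.236826e-03
67.0	6.445183e-02	1.641634e-01	5.131582e-03
68.0	6.154354e-02	1.637213e-01	5.029965e-03
69.0	5.880612e-02	1.632825e-01	4.931801e-03
70.0	5.622725e-02	1.628469e-01	4.836924e-03
71.0	5.379568e-02	1.624146e-01	4.745180e-03
72.0	5.150111e-02	1.619855e-01	4.656422e-03
73.0	4.933405e-02	1.615596e-01	4.570516e-03
74.0	4.728584e-02	1.611368e-01	4.487330e-03
75.0	4.534846e-02	1.607171e-01	4.406745e-03
76.0	4.351457e-02	1.603005e-01	4.328647e-03
77.0	4.177737e-02	1.598869e-01	4.252926e-03
78.0	4.013062e-02	1.594763e-01	4.179482e-03
79.0	3.856854e-02	1.590686e-01	4.108217e-03
80.0	3.708578e-02	1.586639e-01	4.039041e-03
81.0	3.567739e-02	1.582621e-01	3.971868e-03
82.0	3.433879e-02	1.578631e-01	3.906616e-03
83.0	3.306575e-02	1.574670e-01	3.843208e-03
84.0	3.185431e-02	1.570737e-01	3.781569e-03
85.0	3.070081e-02	1.566831e-01	3.721632e-03
86.0	2.960185e-02	1.562953e-01	3.663328e-03
87.0	2.855425e-02	1.559102e-01	3.606597e-03
88.0	2.755508e-02	1.555278e-01	3.551378e-03
89.0	2.660157e-02	1.551480e-01	3.497613e-03
90.0	2.569117e-02	1.547709e-01	3.445250e-03
91.0	2.482147e-02	1.543963e-01	3.394237e-03
92.0	2.399024e-02	1.540244e-01	3.344524e-03
93.0	2.319539e-02	1.536549e-01	3.296065e-03
94.0	2.243496e-02	1.532880e-01	3.248815e-03
95.0	2.170711e-02	1.529236e-01	3.202731e-03
96.0	2.101013e-02	1.525616e-01	3.157774e-03
97.0	2.034240e-02	1.522021e-01	3.113904e-03
98.0	1.970243e-02	1.518450e-01	3.071084e-03
99.0	1.908878e-02	1.514902e-01	3.029279e-03
100.0	1.850013e-02	1.511378e-01	2.988455e-03
101.0	1.793521e-02	1.507878e-01	2.948578e-03
102.0	1.739286e-02	1.504401e-01	2.909619e-03
103.0	1.687197e-02	1.500946e-01	2.871548e-03
104.0	1.637148e-02	1.497514e-01	2.834335e-03
105.0	1.589042e-02	1.494105e-01	2.797953e-03
106.0	1.542786e-02	1.490718e-01	2.762377e-03
107.0	1.498291e-02	1.487353e-01	2.727581e-03
108.0	1.455476e-02	1.484009e-01	2.693541e-03
109.0	1.414263e-02	1.480687e-01	2.660233e-03
110.0	1.374577e-02	1.477386e-01	2.627636e-03
111.0	1.336348e-02	1.474107e-01	2.595728e-03
112.0	1.299512e-02	1.470848e-01	2.564489e-03
113.0	1.264005e-02	1.467610e-01	2.533898e-03
114.0	1.229768e-02	1.464392e-01	2.503936e-03
115.0	1.196746e-02	1.461195e-01	2.474587e-03
116.0	1.164885e-02	1.458017e-01	2.445830e-03
117.0	1.134134e-02	1.454860e-01	2.417651e-03
118.0	1.104447e-02	1.451722e-01	2.390032e-03
119.0	1.075778e-02	1.448604e-01	2.362957e-03
120.0	1.048084e-02	1.445505e-01	2.336412e-03
121.0	1.021323e-02	1.442425e-01	2.310382e-03
122.0	9.954581e-03	1.439364e-01	2.284852e-03
123.0	9.704511e-03	1.436321e-01	2.259810e-03
124.0	9.462673e-03	1.433298e-01	2.235241e-03
125.0	9.228731e-03	1.430292e-01	2.211134e-03
126.0	9.002368e-03	1.427305e-01	2.187476e-03
127.0	8.783282e-03	1.424336e-01	2.164255e-03
128.0	8.571184e-03	1.421384e-01	2.141459e-03
129.0	8.365799e-03	1.418451e-01	2.119078e-03
130.0	8.166865e-03	1.415534e-01	2.097102e-03
131.0	7.974131e-03	1.412635e-01	2.075519e-03
132.0	7.787361e-03	1.409754e-01	2.054320e-03
133.0	7.606325e-03	1.406889e-01	2.033494e-03
134.0	7.430807e-03	1.404041e-01	2.013034e-03
135.0	7.260600e-03	1.401210e-01	1.992929e-03
136.0	7.095504e-03	1.398395e-01	1.973172e-03
137.0	6.935331e-03	1.395597e-01	1.953752e-03
138.0	6.779900e-03	1.392815e-01	1.934663e-03
139.0	6.629036e-03	1.390049e-01	1.915897e-03
140.0	6.482576e-03	1.387299e-01	1.897445e-03
141.0	6.340359e-03	1.384565e-01	1.879300e-03
142.0	6.202235e-03	1.381847e-01	1.861455e-03
143.0	6.068057e-03	1.379144e-01	1.843903e-03
144.0	5.937687e-03	1.376456e-01	1.826637e-03
145.0	5.810992e-03	1.373784e-01	1.809651e-03
146.0	5.687843e-03	1.371126e-01	1.792937e-03
147.0	5.568117e-03	1.368484e-01	1.776491e-03
148.0	5.451699e-03	1.365856e-01	1.760305e-03
149.0	5.338473e-03	1.363243e-01	1.744374e-03
150.0	5.228334e-03	1.360645e-01	1.728693e-03
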