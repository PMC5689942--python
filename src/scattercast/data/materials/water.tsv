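# material: water
# density_g_cm3: 1
# composition: H:0.111898,O:0.888102
# columns: energy_kev photoelectric_cm2_g incoherent_cm2_g coherent_cm2_g
10.0	5.069150e+00	2.140979e-01	4.845802e-02
11.0	3.766426e+00	2.133136e-01	4.260732e-02
12.0	2.871815e+00	2.125369e-01	3.788510e-02
13.0	2.237772e+00	2.117676e-01	3.400466e-02
14.0	1.776266e+00	2.110057e-01	3.076721e-02
15.0	1.432596e+00	2.102509e-01	2.803089e-02
16.0	1.171571e+00	2.095033e-01	2.569196e-02
17.0	9.698644e-01	2.087627e-01	2.367294e-02
18.0	8.116057e-01	2.080291e-01	2.191491e-02
19.0	6.857459e-01	2.073022e-01	2.037227e-02
20.0	5.844346e-01	2.065821e-01	1.900927e-02
21.0	5.019919e-01	2.058686e-01	1.779751e-02
22.0	4.342404e-01	2.051617e-01	1.671414e-02
23.0	3.780621e-01	2.044613e-01	1.574061e-02
24.0	3.310985e-01	2.037672e-01	1.486169e-02
25.0	2.915434e-01	2.030793e-01	1.406481e-02
26.0	2.579981e-01	2.023977e-01	1.333946e-02
27.0	2.293685e-01	2.017222e-01	1.267683e-02
28.0	2.047900e-01	2.010528e-01	1.206946e-02
29.0	1.835741e-01	2.003893e-01	1.151101e-02
30.0	1.651675e-01	1.997316e-01	1.099605e-02
31.0	1.491222e-01	1.990798e-01	1.051990e-02
32.0	1.350733e-01	1.984337e-01	1.007853e-02
33.0	1.227210e-01	1.977932e-01	9.668414e-03
34.0	1.118180e-01	1.971583e-01	9.286501e-03
35.0	1.021589e-01	1.965289e-01	8.930102e-03
36.0	9.357199e-02	1.959049e-01	8.596853e-03
37.0	8.591329e-02	1.952863e-01	8.284669e-03
38.0	7.906130e-02	1.946730e-01	7.991702e-03
39.0	7.291304e-02	1.940649e-01	7.716308e-03
40.0	6.738088e-02	1.934619e-01	7.457022e-03
41.0	6.238991e-02	1.928641e-01	7.212534e-03
42.0	5.787586e-02	1.922712e-01	6.981668e-03
43.0	5.378338e-02	1.916833e-01	6.763368e-03
44.0	5.006462e-02	1.911003e-01	6.556680e-03
45.0	4.667810e-02	1.905222e-01	6.360743e-03
46.0	4.358770e-02	1.899488e-01	6.174779e-03
47.0	4.076191e-02	1.893801e-01	5.998077e-03
48.0	3.817315e-02	1.888161e-01	5.829995e-03
49.0	3.579720e-02	1.882567e-01	5.669945e-03
50.0	3.361274e-02	1.877018e-01	5.517391e-03
51.0	3.160097e-02	1.871515e-01	5.371843e-03
52.0	2.974523e-02	1.866055e-01	5.232850e-03
53.0	2.803076e-02	1.860639e-01	5.099999e-03
54.0	2.644445e-02	1.855267e-01	4.972911e-03
55.0	2.497458e-02	1.849937e-01	4.851235e-03
56.0	2.361074e-02	1.844649e-01	4.734650e-03
57.0	2.234357e-02	1.839403e-01	4.622857e-03
58.0	2.116471e-02	1.834199e-01	4.515579e-03
59.0	2.006662e-02	1.829035e-01	4.412562e-03
60.0	1.904256e-02	1.823911e-01	4.313567e-03
61.0	1.808641e-02	1.818827e-01	4.218376e-03
62.0	1.719266e-02	1.813782e-01	4.126782e-03
63.0	1.635634e-02	1.808776e-01	4.038595e-03
64.0	1.557292e-02	1.803808e-01	3.953638e-03
65.0	1.483832e-02	1.798878e-01	3.871744e-03
66.0	1.414880e-02	1.793986e-01	3.792758e-03
67.0	1.350098e-02	1.789131e-01	3.716535e-03
68.0	1.289177e-02	1.784312e-01	3.642940e-03
69.0	1.231835e-02	1.779529e-01	3.571845e-03
70.0	1.177815e-02	1.774782e-01	3.503130e-03
71.0	1.126880e-02	1.770071e-01	3.436685e-03
72.0	1.078814e-02	1.765395e-01	3.372402e-03
73.0	1.033420e-02	1.760753e-01	3.310184e-03
74.0	9.905152e-03	1.756145e-01	3.249938e-03
75.0	9.499322e-03	1.751571e-01	3.191574e-03
76.0	9.115169e-03	1.747030e-01	3.135012e-03
77.0	8.751272e-03	1.742522e-01	3.080171e-03
78.0	8.406321e-03	1.738047e-01	3.026979e-03
79.0	8.079105e-03	1.733605e-01	2.975366e-03
80.0	7.768505e-03	1.729194e-01	2.925266e-03
81.0	7.473484e-03	1.724815e-01	2.876616e-03
82.0	7.193084e-03	1.720467e-01	2.829357e-03
83.0	6.926414e-03	1.716149e-01	2.783433e-03
84.0	6.672648e-03	1.711863e-01	2.738792e-03
85.0	6.431020e-03	1.707606e-01	2.695382e-03
86.0	6.200816e-03	1.703380e-01	2.653156e-03
87.0	5.981373e-03	1.699183e-01	2.612069e-03
88.0	5.772072e-03	1.695015e-01	2.572076e-03
89.0	5.572337e-03	1.690876e-01	2.533138e-03
90.0	5.381631e-03	1.686766e-01	2.495214e-03
91.0	5.199452e-03	1.682684e-01	2.458267e-03
92.0	5.025331e-03	1.678630e-01	2.422263e-03
93.0	4.858830e-03	1.674604e-01	2.387166e-03
94.0	4.699539e-03	1.670605e-01	2.352946e-03
95.0	4.547074e-03	1.666633e-01	2.319570e-03
96.0	4.401075e-03	1.662688e-01	2.287010e-03
97.0	4.261204e-03	1.658770e-01	2.255237e-03
98.0	4.127146e-03	1.654878e-01	2.224225e-03
99.0	3.998602e-03	1.651012e-01	2.193948e-03
100.0	3.875295e-03	1.647171e-01	2.164381e-03
101.0	3.756960e-03	1.643356e-01	2.135501e-03
102.0	3.643352e-03	1.639567e-01	2.107284e-03
103.0	3.534239e-03	1.635802e-01	2.079711e-03
104.0	3.429400e-03	1.632062e-01	2.052760e-03
105.0	3.328630e-03	1.628346e-01	2.026411e-03
106.0	3.231735e-03	1.624654e-01	2.000645e-03
107.0	3.138531e-03	1.620987e-01	1.975444e-03
108.0	3.048844e-03	1.617343e-01	1.950790e-03
109.0	2.962512e-03	1.613722e-01	1.926667e-03
110.0	2.879380e-03	1.610125e-01	1.903059e-03
111.0	2.799302e-03	1.606551e-01	1.879950e-03
112.0	2.722139e-03	1.602999e-01	1.857324e-03
113.0	2.647761e-03	1.599470e-01	1.835169e-03
114.0	2.576044e-03	1.595964e-01	1.813470e-03
115.0	2.506871e-03	1.592479e-01	1.792213e-03
116.0	2.440130e-03	1.589016e-01	1.771387e-03
117.0	2.375716e-03	1.585575e-01	1.750978e-03
118.0	2.313530e-03	1.582155e-01	1.730974e-03
119.0	2.253475e-03	1.578757e-01	1.711366e-03
120.0	2.195463e-03	1.575379e-01	1.692141e-03
121.0	2.139407e-03	1.572023e-01	1.673288e-03
122.0	2.085226e-03	1.568686e-01	1.654799e-03
123.0	2.032843e-03	1.565371e-01	1.636662e-03
124.0	1.982184e-03	1.562075e-01	1.618868e-03
125.0	1.933179e-03	1.558800e-01	1.601408e-03
126.0	1.885762e-03	1.555544e-01	1.584274e-03
127.0	1.839869e-03	1.552308e-01	1.567456e-03
128.0	1.795440e-03	1.549092e-01	1.550946e-03
129.0	1.752417e-03	1.545894e-01	1.534737e-03
130.0	1.710746e-03	1.542716e-01	1.518821e-03
131.0	1.670373e-03	1.539557e-01	1.503189e-03
132.0	1.631249e-03	1.536416e-01	1.487836e-03
133.0	1.593327e-03	1.533294e-01	1.472753e-03
134.0	1.556561e-03	1.530190e-01	1.457935e-03
135.0	1.520907e-03	1.527105e-01	1.443374e-03
136.0	1.486323e-03	1.524037e-01	1.429065e-03
137.0	1.452771e-03	1.520988e-01	1.415000e-03
138.0	1.420212e-03	1.517956e-01	1.401175e-03
139.0	1.388611e-03	1.514941e-01	1.387583e-03
140.0	1.357931e-03	1.511944e-01	1.374220e-03
141.0	1.328140e-03	1.508964e-01	1.361078e-03
142.0	1.299207e-03	1.506002e-01	1.348154e-03
143.0	1.271100e-03	1.503056e-01	1.335442e-03
144.0	1.243791e-03	1.500127e-01	1.322937e-03
145.0	1.217252e-03	1.497214e-01	1.310635e-03
146.0	1.191455e-03	1.494318e-01	1.298530e-03
147.0	1.166376e-03	1.491438e-01	1.286619e-03
148.0	1.141989e-03	1.488574e-01	1.274896e-03
149.0	1.118271e-03	1.485727e-01	1.263359e-03
150.0	1.095200e-03	1.482895e-01	1.252001e-03
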