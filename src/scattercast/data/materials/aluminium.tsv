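# material: aluminium
# density_g_cm3: 2.699
# composition: Al:1.000000
# columns: energy_kev photoelectric_cm2_g incoherent_cm2_g coherent_cm2_g
10.0	2.865191e+01	1.858314e-01	7.836985e-02
11.0	2.128863e+01	1.851507e-01	6.890767e-02
12.0	1.623210e+01	1.844766e-01	6.127055e-02
13.0	1.264836e+01	1.838088e-01	5.499483e-02
14.0	1.003983e+01	1.831475e-01	4.975898e-02
15.0	8.097336e+00	1.824924e-01	4.533360e-02
16.0	6.621966e+00	1.818435e-01	4.155091e-02
17.0	5.481878e+00	1.812007e-01	3.828561e-02
18.0	4.587367e+00	1.805639e-01	3.544239e-02
19.0	3.875980e+00	1.799330e-01	3.294752e-02
20.0	3.303348e+00	1.793080e-01	3.074319e-02
21.0	2.837364e+00	1.786887e-01	2.878344e-02
22.0	2.454418e+00	1.780751e-01	2.703133e-02
23.0	2.136887e+00	1.774671e-01	2.545686e-02
24.0	1.871439e+00	1.768646e-01	2.403542e-02
25.0	1.647865e+00	1.762676e-01	2.274664e-02
26.0	1.458260e+00	1.756760e-01	2.157355e-02
27.0	1.296439e+00	1.750897e-01	2.050190e-02
28.0	1.157517e+00	1.745086e-01	1.951962e-02
29.0	1.037600e+00	1.739327e-01	1.861645e-02
30.0	9.335614e-01	1.733619e-01	1.778362e-02
31.0	8.428702e-01	1.727961e-01	1.701355e-02
32.0	7.634625e-01	1.722353e-01	1.629973e-02
33.0	6.936449e-01	1.716794e-01	1.563647e-02
34.0	6.320190e-01	1.711283e-01	1.501881e-02
35.0	5.774236e-01	1.705820e-01	1.444241e-02
36.0	5.288886e-01	1.700405e-01	1.390346e-02
37.0	4.856001e-01	1.695035e-01	1.339857e-02
38.0	4.468712e-01	1.689712e-01	1.292476e-02
39.0	4.121199e-01	1.684433e-01	1.247938e-02
40.0	3.808509e-01	1.679200e-01	1.206004e-02
41.0	3.526409e-01	1.674010e-01	1.166464e-02
42.0	3.271266e-01	1.668865e-01	1.129126e-02
43.0	3.039950e-01	1.663762e-01	1.093821e-02
44.0	2.829758e-01	1.658702e-01	1.060394e-02
45.0	2.638345e-01	1.653684e-01	1.028706e-02
46.0	2.463669e-01	1.648707e-01	9.986303e-03
47.0	2.303949e-01	1.643771e-01	9.700529e-03
48.0	2.157627e-01	1.638875e-01	9.428694e-03
49.0	2.023333e-01	1.634020e-01	9.169850e-03
50.0	1.899863e-01	1.629204e-01	8.923128e-03
51.0	1.786154e-01	1.624426e-01	8.687736e-03
52.0	1.681263e-01	1.619688e-01	8.462946e-03
53.0	1.584358e-01	1.614987e-01	8.248090e-03
54.0	1.494696e-01	1.610324e-01	8.042554e-03
55.0	1.411616e-01	1.605698e-01	7.845772e-03
56.0	1.334529e-01	1.601108e-01	7.657222e-03
57.0	1.262906e-01	1.596555e-01	7.476421e-03
58.0	1.196274e-01	1.592037e-01	7.302924e-03
59.0	1.134208e-01	1.587555e-01	7.136317e-03
60.0	1.076326e-01	1.583108e-01	6.976216e-03
61.0	1.022282e-01	1.578695e-01	6.822265e-03
62.0	9.717655e-02	1.574316e-01	6.674133e-03
63.0	9.244948e-02	1.569971e-01	6.531512e-03
64.0	8.802145e-02	1.565659e-01	6.394112e-03
65.0	8.386930e-02	1.561380e-01	6.261667e-03
66.0	7.997200e-02	1.557134e-01	6.133925e-03
67.0	7.631039e-02	1.552919e-01	6.010652e-03
68.0	7.286701e-02	1.548737e-01	5.891628e-03
69.0	6.962592e-02	1.544586e-01	5.776648e-03
70.0	6.657256e-02	1.540466e-01	5.665518e-03
71.0	6.369361e-02	1.536376e-01	5.558057e-03
72.0	6.097685e-02	1.532317e-01	5.454095e-03
73.0	5.841108e-02	1.528288e-01	5.353472e-03
74.0	5.598601e-02	1.524288e-01	5.256037e-03
75.0	5.369217e-02	1.520318e-01	5.161647e-03
76.0	5.152086e-02	1.516377e-01	5.070170e-03
77.0	4.946404e-02	1.512465e-01	4.981477e-03
78.0	4.751430e-02	1.508580e-01	4.895452e-03
79.0	4.566481e-02	1.504724e-01	4.811979e-03
80.0	4.390923e-02	1.500896e-01	4.730953e-03
81.0	4.224171e-02	1.497095e-01	4.652273e-03
82.0	4.065683e-02	1.493321e-01	4.575843e-03
83.0	3.914955e-02	1.489574e-01	4.501572e-03
84.0	3.771522e-02	1.485853e-01	4.429375e-03
85.0	3.634948e-02	1.482158e-01	4.359169e-03
86.0	3.504832e-02	1.478490e-01	4.290878e-03
87.0	3.380798e-02	1.474847e-01	4.224429e-03
88.0	3.262497e-02	1.471229e-01	4.159750e-03
89.0	3.149603e-02	1.467637e-01	4.096775e-03
90.0	3.041812e-02	1.464069e-01	4.035442e-03
91.0	2.938840e-02	1.460526e-01	3.975689e-03
92.0	2.840423e-02	1.457008e-01	3.917460e-03
93.0	2.746314e-02	1.453513e-01	3.860700e-03
94.0	2.656279e-02	1.450042e-01	3.805356e-03
95.0	2.570102e-02	1.446595e-01	3.751378e-03
96.0	2.487580e-02	1.443171e-01	3.698720e-03
97.0	2.408523e-02	1.439770e-01	3.647335e-03
98.0	2.332750e-02	1.436391e-01	3.597179e-03
99.0	2.260095e-02	1.433036e-01	3.548213e-03
100.0	2.190398e-02	1.429702e-01	3.500395e-03
101.0	2.123513e-02	1.426391e-01	3.453687e-03
102.0	2.059300e-02	1.423102e-01	3.408054e-03
103.0	1.997626e-02	1.419834e-01	3.363461e-03
104.0	1.938369e-02	1.416588e-01	3.319873e-03
105.0	1.881412e-02	1.413362e-01	3.277259e-03
106.0	1.826645e-02	1.410158e-01	3.235589e-03
107.0	1.773964e-02	1.406975e-01	3.194832e-03
108.0	1.723271e-02	1.403812e-01	3.154960e-03
109.0	1.674475e-02	1.400670e-01	3.115947e-03
110.0	1.627487e-02	1.397547e-01	3.077766e-03
111.0	1.582225e-02	1.394445e-01	3.040392e-03
112.0	1.538611e-02	1.391362e-01	3.003801e-03
113.0	1.496571e-02	1.388299e-01	2.967969e-03
114.0	1.456035e-02	1.385255e-01	2.932876e-03
115.0	1.416936e-02	1.382231e-01	2.898498e-03
116.0	1.379213e-02	1.379225e-01	2.864816e-03
117.0	1.342805e-02	1.376238e-01	2.831809e-03
118.0	1.307656e-02	1.373270e-01	2.799458e-03
119.0	1.273712e-02	1.370320e-01	2.767746e-03
120.0	1.240922e-02	1.367389e-01	2.736653e-03
121.0	1.209238e-02	1.364475e-01	2.706164e-03
122.0	1.178614e-02	1.361579e-01	2.676261e-03
123.0	1.149006e-02	1.358702e-01	2.646929e-03
124.0	1.120372e-02	1.355841e-01	2.618151e-03
125.0	1.092674e-02	1.352998e-01	2.589914e-03
126.0	1.065872e-02	1.350172e-01	2.562203e-03
127.0	1.039933e-02	1.347364e-01	2.535004e-03
128.0	1.014821e-02	1.344572e-01	2.508304e-03
129.0	9.905032e-03	1.341796e-01	2.482089e-03
130.0	9.669495e-03	1.339038e-01	2.456348e-03
131.0	9.441301e-03	1.336296e-01	2.431068e-03
132.0	9.220166e-03	1.333570e-01	2.406237e-03
133.0	9.005821e-03	1.330860e-01	2.381844e-03
134.0	8.798010e-03	1.328166e-01	2.357879e-03
135.0	8.596485e-03	1.325488e-01	2.334330e-03
136.0	8.401014e-03	1.322825e-01	2.311188e-03
137.0	8.211370e-03	1.320178e-01	2.288442e-03
138.0	8.027341e-03	1.317546e-01	2.266083e-03
139.0	7.848720e-03	1.314930e-01	2.244101e-03
140.0	7.675312e-03	1.312329e-01	2.222488e-03
141.0	7.506929e-03	1.309742e-01	2.201235e-03
142.0	7.343391e-03	1.307171e-01	2.180333e-03
143.0	7.184526e-03	1.304614e-01	2.159774e-03
144.0	7.030169e-03	1.302071e-01	2.139551e-03
145.0	6.880162e-03	1.299543e-01	2.119654e-03
146.0	6.734355e-03	1.297029e-01	2.100078e-03
147.0	6.592601e-03	1.294530e-01	2.080814e-03
148.0	6.454763e-03	1.292044e-01	2.061856e-03
149.0	6.320705e-03	1.289573e-01	2.043196e-03
150.0	6.190301e-03	1.287115e-01	2.024828e-03
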