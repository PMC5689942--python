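# material: carbon_table
# density_g_cm3: 0.55
# composition: H:0.030000,C:0.910000,O:0.060000
# columns: energy_kev photoelectric_cm2_g incoherent_cm2_g coherent_cm2_g
10.0	2.293450e+00	1.983838e-01	4.050442e-02
11.0	1.704055e+00	1.976571e-01	3.561402e-02
12.0	1.299304e+00	1.969374e-01	3.166688e-02
13.0	1.012442e+00	1.962246e-01	2.842335e-02
14.0	8.036413e-01	1.955186e-01	2.571727e-02
15.0	6.481536e-01	1.948192e-01	2.343007e-02
16.0	5.300573e-01	1.941265e-01	2.147504e-02
17.0	4.387986e-01	1.934403e-01	1.978741e-02
18.0	3.671971e-01	1.927605e-01	1.831793e-02
19.0	3.102540e-01	1.920870e-01	1.702849e-02
20.0	2.644174e-01	1.914197e-01	1.588921e-02
21.0	2.271177e-01	1.907586e-01	1.487634e-02
22.0	1.964646e-01	1.901036e-01	1.397079e-02
23.0	1.710478e-01	1.894545e-01	1.315704e-02
24.0	1.497999e-01	1.888113e-01	1.242239e-02
25.0	1.319038e-01	1.881740e-01	1.175630e-02
26.0	1.167269e-01	1.875424e-01	1.115001e-02
27.0	1.037738e-01	1.869165e-01	1.059614e-02
28.0	9.265375e-02	1.862962e-01	1.008846e-02
29.0	8.305498e-02	1.856814e-01	9.621668e-03
30.0	7.472720e-02	1.850720e-01	9.191227e-03
31.0	6.746780e-02	1.844680e-01	8.793231e-03
32.0	6.111159e-02	1.838693e-01	8.424300e-03
33.0	5.552301e-02	1.832759e-01	8.081502e-03
34.0	5.059015e-02	1.826876e-01	7.762273e-03
35.0	4.622004e-02	1.821044e-01	7.464371e-03
36.0	4.233505e-02	1.815262e-01	7.185819e-03
37.0	3.887000e-02	1.809530e-01	6.924875e-03
38.0	3.576994e-02	1.803847e-01	6.679994e-03
39.0	3.298826e-02	1.798212e-01	6.449801e-03
40.0	3.048533e-02	1.792625e-01	6.233073e-03
41.0	2.822725e-02	1.787085e-01	6.028714e-03
42.0	2.618494e-02	1.781592e-01	5.835741e-03
43.0	2.433337e-02	1.776144e-01	5.653271e-03
44.0	2.265088e-02	1.770742e-01	5.480507e-03
45.0	2.111871e-02	1.765385e-01	5.316731e-03
46.0	1.972051e-02	1.760072e-01	5.161289e-03
47.0	1.844203e-02	1.754803e-01	5.013590e-03
48.0	1.727079e-02	1.749577e-01	4.873096e-03
49.0	1.619583e-02	1.744393e-01	4.739316e-03
50.0	1.520751e-02	1.739252e-01	4.611801e-03
51.0	1.429732e-02	1.734152e-01	4.490142e-03
52.0	1.345772e-02	1.729093e-01	4.373962e-03
53.0	1.268204e-02	1.724075e-01	4.262917e-03
54.0	1.196434e-02	1.719097e-01	4.156688e-03
55.0	1.129932e-02	1.714158e-01	4.054984e-03
56.0	1.068228e-02	1.709258e-01	3.957534e-03
57.0	1.010897e-02	1.704397e-01	3.864090e-03
58.0	9.575610e-03	1.699575e-01	3.774420e-03
59.0	9.078802e-03	1.694790e-01	3.688311e-03
60.0	8.615480e-03	1.690042e-01	3.605565e-03
61.0	8.182886e-03	1.685331e-01	3.525998e-03
62.0	7.778526e-03	1.680656e-01	3.449438e-03
63.0	7.400146e-03	1.676018e-01	3.375726e-03
64.0	7.045703e-03	1.671415e-01	3.304713e-03
65.0	6.713343e-03	1.666847e-01	3.236260e-03
66.0	6.401383e-03	1.662313e-01	3.170239e-03
67.0	6.108288e-03	1.657815e-01	3.106526e-03
68.0	5.832661e-03	1.653349e-01	3.045011e-03
69.0	5.573227e-03	1.648918e-01	2.985584e-03
70.0	5.328821e-03	1.644520e-01	2.928148e-03
71.0	5.098374e-03	1.640154e-01	2.872609e-03
72.0	4.880910e-03	1.635821e-01	2.818877e-03
73.0	4.675532e-03	1.631519e-01	2.766871e-03
74.0	4.481417e-03	1.627250e-01	2.716513e-03
75.0	4.297806e-03	1.623011e-01	2.667729e-03
76.0	4.124002e-03	1.618804e-01	2.620450e-03
77.0	3.959364e-03	1.614627e-01	2.574611e-03
78.0	3.803296e-03	1.610481e-01	2.530150e-03
79.0	3.655253e-03	1.606364e-01	2.487008e-03
80.0	3.514727e-03	1.602277e-01	2.445131e-03
81.0	3.381250e-03	1.598219e-01	2.404466e-03
82.0	3.254388e-03	1.594190e-01	2.364964e-03
83.0	3.133738e-03	1.590190e-01	2.326578e-03
84.0	3.018926e-03	1.586218e-01	2.289264e-03
85.0	2.909605e-03	1.582274e-01	2.252979e-03
86.0	2.805453e-03	1.578358e-01	2.217684e-03
87.0	2.706170e-03	1.574469e-01	2.183340e-03
88.0	2.611475e-03	1.570607e-01	2.149912e-03
89.0	2.521109e-03	1.566772e-01	2.117364e-03
90.0	2.434827e-03	1.562963e-01	2.085665e-03
91.0	2.352403e-03	1.559181e-01	2.054783e-03
92.0	2.273625e-03	1.555424e-01	2.024688e-03
93.0	2.198295e-03	1.551694e-01	1.995352e-03
94.0	2.126226e-03	1.547988e-01	1.966748e-03
95.0	2.057246e-03	1.544308e-01	1.938851e-03
96.0	1.991191e-03	1.540653e-01	1.911635e-03
97.0	1.927909e-03	1.537022e-01	1.885077e-03
98.0	1.867257e-03	1.533416e-01	1.859155e-03
99.0	1.809099e-03	1.529833e-01	1.833847e-03
100.0	1.753311e-03	1.526275e-01	1.809133e-03
101.0	1.699773e-03	1.522740e-01	1.784993e-03
102.0	1.648373e-03	1.519228e-01	1.761408e-03
103.0	1.599006e-03	1.515740e-01	1.738360e-03
104.0	1.551573e-03	1.512274e-01	1.715833e-03
105.0	1.505982e-03	1.508831e-01	1.693808e-03
106.0	1.462143e-03	1.505410e-01	1.672271e-03
107.0	1.419975e-03	1.502012e-01	1.651207e-03
108.0	1.379398e-03	1.498636e-01	1.630600e-03
109.0	1.340338e-03	1.495281e-01	1.610436e-03
110.0	1.302726e-03	1.491948e-01	1.590703e-03
111.0	1.266496e-03	1.488636e-01	1.571386e-03
112.0	1.231585e-03	1.485345e-01	1.552475e-03
113.0	1.197934e-03	1.482075e-01	1.533956e-03
114.0	1.165487e-03	1.478825e-01	1.515818e-03
115.0	1.134191e-03	1.475596e-01	1.498050e-03
116.0	1.103995e-03	1.472388e-01	1.480642e-03
117.0	1.074852e-03	1.469199e-01	1.463583e-03
118.0	1.046717e-03	1.466031e-01	1.446863e-03
119.0	1.019546e-03	1.462881e-01	1.430473e-03
120.0	9.932996e-04	1.459752e-01	1.414403e-03
121.0	9.679380e-04	1.456642e-01	1.398645e-03
122.0	9.434247e-04	1.453550e-01	1.383190e-03
123.0	9.197249e-04	1.450478e-01	1.368030e-03
124.0	8.968051e-04	1.447424e-01	1.353157e-03
125.0	8.746338e-04	1.444389e-01	1.338563e-03
126.0	8.531807e-04	1.441373e-01	1.324241e-03
127.0	8.324173e-04	1.438374e-01	1.310184e-03
128.0	8.123162e-04	1.435394e-01	1.296384e-03
129.0	7.928512e-04	1.432431e-01	1.282835e-03
130.0	7.739976e-04	1.429486e-01	1.269531e-03
131.0	7.557317e-04	1.426558e-01	1.256465e-03
132.0	7.380309e-04	1.423648e-01	1.243632e-03
133.0	7.208736e-04	1.420755e-01	1.231025e-03
134.0	7.042393e-04	1.417880e-01	1.218639e-03
135.0	6.881082e-04	1.415020e-01	1.206468e-03
136.0	6.724616e-04	1.412178e-01	1.194507e-03
137.0	6.572816e-04	1.409352e-01	1.182751e-03
138.0	6.425509e-04	1.406543e-01	1.171195e-03
139.0	6.282531e-04	1.403750e-01	1.159834e-03
140.0	6.143726e-04	1.400973e-01	1.148664e-03
141.0	6.008943e-04	1.398212e-01	1.137679e-03
142.0	5.878039e-04	1.395466e-01	1.126877e-03
143.0	5.750875e-04	1.392737e-01	1.116251e-03
144.0	5.627320e-04	1.390022e-01	1.105799e-03
145.0	5.507247e-04	1.387324e-01	1.095515e-03
146.0	5.390535e-04	1.384640e-01	1.085398e-03
147.0	5.277067e-04	1.381972e-01	1.075441e-03
148.0	5.166734e-04	1.379318e-01	1.065643e-03
149.0	5.059427e-04	1.376680e-01	1.055999e-03
150.0	4.955045e-04	1.374056e-01	1.046506e-03
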