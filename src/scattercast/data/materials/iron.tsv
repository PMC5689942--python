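# material: iron
# density_g_cm3: 7.874
# composition: Fe:1.000000
# columns: energy_kev photoelectric_cm2_g incoherent_cm2_g coherent_cm2_g
10.0	2.922640e+02	1.795722e-01	1.413175e-01
11.0	2.171549e+02	1.789144e-01	1.242551e-01
12.0	1.655757e+02	1.782629e-01	1.104838e-01
13.0	1.290197e+02	1.776177e-01	9.916734e-02
14.0	1.024114e+02	1.769786e-01	8.972600e-02
15.0	8.259694e+01	1.763456e-01	8.174609e-02
16.0	6.754742e+01	1.757186e-01	7.492510e-02
17.0	5.591795e+01	1.750974e-01	6.903708e-02
18.0	4.679347e+01	1.744820e-01	6.391014e-02
19.0	3.953697e+01	1.738724e-01	5.941137e-02
20.0	3.369583e+01	1.732684e-01	5.543649e-02
21.0	2.894256e+01	1.726700e-01	5.190264e-02
22.0	2.503631e+01	1.720771e-01	4.874323e-02
23.0	2.179733e+01	1.714896e-01	4.590412e-02
24.0	1.908963e+01	1.709074e-01	4.334096e-02
25.0	1.680906e+01	1.703305e-01	4.101702e-02
26.0	1.487499e+01	1.697588e-01	3.890170e-02
27.0	1.322434e+01	1.691923e-01	3.696928e-02
28.0	1.180726e+01	1.686307e-01	3.519802e-02
29.0	1.058405e+01	1.680742e-01	3.356941e-02
30.0	9.522801e+00	1.675227e-01	3.206763e-02
31.0	8.597705e+00	1.669759e-01	3.067905e-02
32.0	7.787706e+00	1.664340e-01	2.939187e-02
33.0	7.075531e+00	1.658968e-01	2.819587e-02
34.0	6.446916e+00	1.653643e-01	2.708210e-02
35.0	5.890014e+00	1.648364e-01	2.604273e-02
36.0	5.394933e+00	1.643131e-01	2.507089e-02
37.0	4.953368e+00	1.637942e-01	2.416047e-02
38.0	4.558313e+00	1.632798e-01	2.330609e-02
39.0	4.203833e+00	1.627697e-01	2.250296e-02
40.0	3.884873e+00	1.622640e-01	2.174681e-02
41.0	3.597117e+00	1.617626e-01	2.103381e-02
42.0	3.336857e+00	1.612653e-01	2.036054e-02
43.0	3.100904e+00	1.607722e-01	1.972392e-02
44.0	2.886497e+00	1.602833e-01	1.912116e-02
45.0	2.691246e+00	1.597983e-01	1.854975e-02
46.0	2.513067e+00	1.593174e-01	1.800742e-02
47.0	2.350145e+00	1.588405e-01	1.749211e-02
48.0	2.200889e+00	1.583674e-01	1.700194e-02
49.0	2.063903e+00	1.578982e-01	1.653518e-02
50.0	1.937957e+00	1.574328e-01	1.609029e-02
51.0	1.821967e+00	1.569712e-01	1.566583e-02
52.0	1.714974e+00	1.565133e-01	1.526049e-02
53.0	1.616126e+00	1.560590e-01	1.487306e-02
54.0	1.524666e+00	1.556084e-01	1.450243e-02
55.0	1.439920e+00	1.551614e-01	1.414759e-02
56.0	1.361287e+00	1.547179e-01	1.380760e-02
57.0	1.288228e+00	1.542779e-01	1.348157e-02
58.0	1.220260e+00	1.538413e-01	1.316872e-02
59.0	1.156950e+00	1.534082e-01	1.286829e-02
60.0	1.097907e+00	1.529784e-01	1.257960e-02
61.0	1.042780e+00	1.525520e-01	1.230199e-02
62.0	9.912502e-01	1.521289e-01	1.203488e-02
63.0	9.430317e-01	1.517090e-01	1.177770e-02
64.0	8.978635e-01	1.512924e-01	1.152994e-02
65.0	8.555095e-01	1.508789e-01	1.129111e-02
66.0	8.157551e-01	1.504685e-01	1.106077e-02
67.0	7.784048e-01	1.500613e-01	1.083848e-02
68.0	7.432805e-01	1.496571e-01	1.062386e-02
69.0	7.102198e-01	1.492560e-01	1.041652e-02
70.0	6.790740e-01	1.488579e-01	1.021613e-02
71.0	6.497072e-01	1.484627e-01	1.002236e-02
72.0	6.219949e-01	1.480705e-01	9.834891e-03
73.0	5.958227e-01	1.476811e-01	9.653446e-03
74.0	5.710858e-01	1.472947e-01	9.477749e-03
75.0	5.476875e-01	1.469110e-01	9.307545e-03
76.0	5.255390e-01	1.465302e-01	9.142592e-03
77.0	5.045583e-01	1.461521e-01	8.982661e-03
78.0	4.846700e-01	1.457768e-01	8.827538e-03
79.0	4.658043e-01	1.454041e-01	8.677019e-03
80.0	4.478965e-01	1.450342e-01	8.530912e-03
81.0	4.308869e-01	1.446669e-01	8.389035e-03
82.0	4.147203e-01	1.443022e-01	8.251215e-03
83.0	3.993453e-01	1.439401e-01	8.117289e-03
84.0	3.847144e-01	1.435806e-01	7.987102e-03
85.0	3.707832e-01	1.432236e-01	7.860507e-03
86.0	3.575107e-01	1.428691e-01	7.737364e-03
87.0	3.448586e-01	1.425170e-01	7.617541e-03
88.0	3.327913e-01	1.421675e-01	7.500911e-03
89.0	3.212755e-01	1.418203e-01	7.387355e-03
90.0	3.102802e-01	1.414756e-01	7.276758e-03
91.0	2.997766e-01	1.411332e-01	7.169012e-03
92.0	2.897376e-01	1.407932e-01	7.064012e-03
93.0	2.801379e-01	1.404555e-01	6.961661e-03
94.0	2.709540e-01	1.401201e-01	6.861864e-03
95.0	2.621635e-01	1.397870e-01	6.764531e-03
96.0	2.537459e-01	1.394561e-01	6.669576e-03
97.0	2.456816e-01	1.391275e-01	6.576918e-03
98.0	2.379524e-01	1.388010e-01	6.486478e-03
99.0	2.305411e-01	1.384767e-01	6.398180e-03
100.0	2.234318e-01	1.381546e-01	6.311954e-03
101.0	2.166092e-01	1.378347e-01	6.227731e-03
102.0	2.100590e-01	1.375168e-01	6.145445e-03
103.0	2.037680e-01	1.372010e-01	6.065033e-03
104.0	1.977235e-01	1.368873e-01	5.986435e-03
105.0	1.919136e-01	1.365757e-01	5.909594e-03
106.0	1.863271e-01	1.362661e-01	5.834453e-03
107.0	1.809533e-01	1.359584e-01	5.760959e-03
108.0	1.757824e-01	1.356528e-01	5.689063e-03
109.0	1.708049e-01	1.353491e-01	5.618713e-03
110.0	1.660119e-01	1.350474e-01	5.549865e-03
111.0	1.613950e-01	1.347476e-01	5.482472e-03
112.0	1.569461e-01	1.344498e-01	5.416490e-03
113.0	1.526578e-01	1.341538e-01	5.351879e-03
114.0	1.485229e-01	1.338596e-01	5.288597e-03
115.0	1.445347e-01	1.335674e-01	5.226607e-03
116.0	1.406868e-01	1.332769e-01	5.165870e-03
117.0	1.369729e-01	1.329883e-01	5.106352e-03
118.0	1.333875e-01	1.327015e-01	5.048017e-03
119.0	1.299251e-01	1.324164e-01	4.990833e-03
120.0	1.265803e-01	1.321332e-01	4.934767e-03
121.0	1.233484e-01	1.318516e-01	4.879788e-03
122.0	1.202246e-01	1.315718e-01	4.825867e-03
123.0	1.172044e-01	1.312937e-01	4.772974e-03
124.0	1.142836e-01	1.310173e-01	4.721083e-03
125.0	1.114583e-01	1.307426e-01	4.670165e-03
126.0	1.087244e-01	1.304695e-01	4.620196e-03
127.0	1.060784e-01	1.301981e-01	4.571150e-03
128.0	1.035169e-01	1.299283e-01	4.523004e-03
129.0	1.010364e-01	1.296601e-01	4.475733e-03
130.0	9.863377e-02	1.293936e-01	4.429316e-03
131.0	9.630607e-02	1.291286e-01	4.383731e-03
132.0	9.405038e-02	1.288652e-01	4.338955e-03
133.0	9.186396e-02	1.286033e-01	4.294970e-03
134.0	8.974417e-02	1.283430e-01	4.251756e-03
135.0	8.768852e-02	1.280842e-01	4.209292e-03
136.0	8.569461e-02	1.278269e-01	4.167562e-03
137.0	8.376015e-02	1.275711e-01	4.126546e-03
138.0	8.188296e-02	1.273168e-01	4.086228e-03
139.0	8.006094e-02	1.270640e-01	4.046591e-03
140.0	7.829209e-02	1.268126e-01	4.007618e-03
141.0	7.657449e-02	1.265627e-01	3.969294e-03
142.0	7.490632e-02	1.263142e-01	3.931604e-03
143.0	7.328582e-02	1.260671e-01	3.894532e-03
144.0	7.171130e-02	1.258214e-01	3.858064e-03
145.0	7.018116e-02	1.255771e-01	3.822187e-03
146.0	6.869385e-02	1.253342e-01	3.786886e-03
147.0	6.724789e-02	1.250927e-01	3.752149e-03
148.0	6.584186e-02	1.248525e-01	3.717963e-03
149.0	6.447441e-02	1.246137e-01	3.684316e-03
150.0	6.314421e-02	1.243761e-01	3.651195e-03
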