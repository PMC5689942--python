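# material: pmma
# density_g_cm3: 1.19
# composition: H:0.080538,C:0.599848,O:0.319614
# columns: energy_kev photoelectric_cm2_g incoherent_cm2_g coherent_cm2_g
10.0	3.110587e+00	2.080333e-01	4.238941e-02
11.0	2.311195e+00	2.072712e-01	3.727142e-02
12.0	1.762234e+00	2.065165e-01	3.314058e-02
13.0	1.373166e+00	2.057691e-01	2.974611e-02
14.0	1.089972e+00	2.050287e-01	2.691410e-02
15.0	8.790853e-01	2.042953e-01	2.452046e-02
16.0	7.189122e-01	2.035689e-01	2.247444e-02
17.0	5.951388e-01	2.028493e-01	2.070828e-02
18.0	4.980263e-01	2.021364e-01	1.917041e-02
19.0	4.207949e-01	2.014301e-01	1.782096e-02
20.0	3.586271e-01	2.007304e-01	1.662866e-02
21.0	3.080377e-01	2.000372e-01	1.556865e-02
22.0	2.664633e-01	1.993503e-01	1.462096e-02
23.0	2.319906e-01	1.986696e-01	1.376934e-02
24.0	2.031723e-01	1.979952e-01	1.300050e-02
25.0	1.789000e-01	1.973269e-01	1.230341e-02
26.0	1.583156e-01	1.966646e-01	1.166890e-02
27.0	1.407476e-01	1.960082e-01	1.108926e-02
28.0	1.256655e-01	1.953577e-01	1.055795e-02
29.0	1.126468e-01	1.947130e-01	1.006944e-02
30.0	1.013519e-01	1.940740e-01	9.618967e-03
31.0	9.150600e-02	1.934406e-01	9.202448e-03
32.0	8.288512e-02	1.928128e-01	8.816348e-03
33.0	7.530539e-02	1.921905e-01	8.457597e-03
34.0	6.861499e-02	1.915736e-01	8.123512e-03
35.0	6.268785e-02	1.909620e-01	7.811746e-03
36.0	5.741866e-02	1.903557e-01	7.520231e-03
37.0	5.271905e-02	1.897546e-01	7.247144e-03
38.0	4.851446e-02	1.891587e-01	6.990866e-03
39.0	4.474170e-02	1.885678e-01	6.749961e-03
40.0	4.134699e-02	1.879819e-01	6.523146e-03
41.0	3.828438e-02	1.874010e-01	6.309277e-03
42.0	3.551442e-02	1.868249e-01	6.107323e-03
43.0	3.300314e-02	1.862537e-01	5.916361e-03
44.0	3.072120e-02	1.856872e-01	5.735558e-03
45.0	2.864312e-02	1.851254e-01	5.564160e-03
46.0	2.674676e-02	1.845683e-01	5.401484e-03
47.0	2.501277e-02	1.840157e-01	5.246912e-03
48.0	2.342422e-02	1.834677e-01	5.099880e-03
49.0	2.196627e-02	1.829241e-01	4.959873e-03
50.0	2.062582e-02	1.823850e-01	4.826424e-03
51.0	1.939133e-02	1.818502e-01	4.699103e-03
52.0	1.825259e-02	1.813197e-01	4.577517e-03
53.0	1.720054e-02	1.807934e-01	4.461304e-03
54.0	1.622713e-02	1.802714e-01	4.350131e-03
55.0	1.532518e-02	1.797535e-01	4.243694e-03
56.0	1.448828e-02	1.792397e-01	4.141709e-03
57.0	1.371071e-02	1.787300e-01	4.043916e-03
58.0	1.298732e-02	1.782243e-01	3.950073e-03
59.0	1.231350e-02	1.777225e-01	3.859957e-03
60.0	1.168510e-02	1.772246e-01	3.773360e-03
61.0	1.109838e-02	1.767306e-01	3.690090e-03
62.0	1.054995e-02	1.762404e-01	3.609967e-03
63.0	1.003675e-02	1.757540e-01	3.532825e-03
64.0	9.556027e-03	1.752713e-01	3.458507e-03
65.0	9.105250e-03	1.747923e-01	3.386869e-03
66.0	8.682141e-03	1.743169e-01	3.317774e-03
67.0	8.284619e-03	1.738451e-01	3.251097e-03
68.0	7.910789e-03	1.733769e-01	3.186719e-03
69.0	7.558921e-03	1.729122e-01	3.124527e-03
70.0	7.227434e-03	1.724510e-01	3.064418e-03
71.0	6.914881e-03	1.719932e-01	3.006293e-03
72.0	6.619937e-03	1.715388e-01	2.950062e-03
73.0	6.341385e-03	1.710877e-01	2.895636e-03
74.0	6.078107e-03	1.706400e-01	2.842934e-03
75.0	5.829078e-03	1.701955e-01	2.791880e-03
76.0	5.593349e-03	1.697543e-01	2.742400e-03
77.0	5.370051e-03	1.693163e-01	2.694428e-03
78.0	5.158379e-03	1.688815e-01	2.647897e-03
79.0	4.957589e-03	1.684498e-01	2.602748e-03
80.0	4.766995e-03	1.680212e-01	2.558922e-03
81.0	4.585961e-03	1.675957e-01	2.516364e-03
82.0	4.413898e-03	1.671732e-01	2.475024e-03
83.0	4.250261e-03	1.667537e-01	2.434852e-03
84.0	4.094543e-03	1.663372e-01	2.395801e-03
85.0	3.946273e-03	1.659236e-01	2.357828e-03
86.0	3.805013e-03	1.655130e-01	2.320890e-03
87.0	3.670355e-03	1.651051e-01	2.284948e-03
88.0	3.541922e-03	1.647002e-01	2.249964e-03
89.0	3.419358e-03	1.642980e-01	2.215902e-03
90.0	3.302335e-03	1.638986e-01	2.182727e-03
91.0	3.190545e-03	1.635020e-01	2.150408e-03
92.0	3.083699e-03	1.631081e-01	2.118912e-03
93.0	2.981529e-03	1.627169e-01	2.088211e-03
94.0	2.883783e-03	1.623283e-01	2.058276e-03
95.0	2.790225e-03	1.619424e-01	2.029080e-03
96.0	2.700636e-03	1.615591e-01	2.000598e-03
97.0	2.614807e-03	1.611783e-01	1.972804e-03
98.0	2.532544e-03	1.608001e-01	1.945676e-03
99.0	2.453666e-03	1.604245e-01	1.919190e-03
100.0	2.378001e-03	1.600513e-01	1.893326e-03
101.0	2.305387e-03	1.596806e-01	1.868062e-03
102.0	2.235674e-03	1.593124e-01	1.843380e-03
103.0	2.168718e-03	1.589466e-01	1.819260e-03
104.0	2.104386e-03	1.585832e-01	1.795684e-03
105.0	2.042550e-03	1.582221e-01	1.772634e-03
106.0	1.983092e-03	1.578634e-01	1.750095e-03
107.0	1.925899e-03	1.575070e-01	1.728050e-03
108.0	1.870865e-03	1.571530e-01	1.706484e-03
109.0	1.817889e-03	1.568012e-01	1.685382e-03
110.0	1.766877e-03	1.564516e-01	1.664731e-03
111.0	1.717738e-03	1.561043e-01	1.644515e-03
112.0	1.670389e-03	1.557592e-01	1.624724e-03
113.0	1.624748e-03	1.554163e-01	1.605343e-03
114.0	1.580741e-03	1.550756e-01	1.586361e-03
115.0	1.538294e-03	1.547370e-01	1.567766e-03
116.0	1.497339e-03	1.544005e-01	1.549548e-03
117.0	1.457813e-03	1.540662e-01	1.531695e-03
118.0	1.419653e-03	1.537339e-01	1.514197e-03
119.0	1.382802e-03	1.534037e-01	1.497044e-03
120.0	1.347204e-03	1.530755e-01	1.480227e-03
121.0	1.312806e-03	1.527493e-01	1.463735e-03
122.0	1.279559e-03	1.524252e-01	1.447561e-03
123.0	1.247415e-03	1.521030e-01	1.431695e-03
124.0	1.216329e-03	1.517828e-01	1.416130e-03
125.0	1.186258e-03	1.514645e-01	1.400857e-03
126.0	1.157162e-03	1.511482e-01	1.385868e-03
127.0	1.129001e-03	1.508337e-01	1.371157e-03
128.0	1.101737e-03	1.505212e-01	1.356715e-03
129.0	1.075337e-03	1.502105e-01	1.342535e-03
130.0	1.049766e-03	1.499017e-01	1.328612e-03
131.0	1.024993e-03	1.495947e-01	1.314938e-03
132.0	1.000985e-03	1.492895e-01	1.301508e-03
133.0	9.777148e-04	1.489862e-01	1.288314e-03
134.0	9.551538e-04	1.486846e-01	1.275351e-03
135.0	9.332753e-04	1.483848e-01	1.262614e-03
136.0	9.120540e-04	1.480867e-01	1.250097e-03
137.0	8.914654e-04	1.477904e-01	1.237794e-03
138.0	8.714863e-04	1.474958e-01	1.225700e-03
139.0	8.520944e-04	1.472029e-01	1.213810e-03
140.0	8.332684e-04	1.469117e-01	1.202120e-03
141.0	8.149879e-04	1.466221e-01	1.190625e-03
142.0	7.972334e-04	1.463342e-01	1.179319e-03
143.0	7.799863e-04	1.460480e-01	1.168199e-03
144.0	7.632286e-04	1.457634e-01	1.157260e-03
145.0	7.469432e-04	1.454804e-01	1.146498e-03
146.0	7.311136e-04	1.451990e-01	1.135910e-03
147.0	7.157242e-04	1.449191e-01	1.125490e-03
148.0	7.007597e-04	1.446409e-01	1.115236e-03
149.0	6.862058e-04	1.443642e-01	1.105143e-03
150.0	6.720485e-04	1.440890e-01	1.095208e-03
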