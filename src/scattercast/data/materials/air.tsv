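# material: air
# density_g_cm3: 0.0012047
# composition: C:0.000124,N:0.755267,O:0.231781,Ar:0.012827
# columns: energy_kev photoelectric_cm2_g incoherent_cm2_g coherent_cm2_g
10.0	5.097841e+00	1.925355e-01	4.861335e-02
11.0	3.787744e+00	1.918302e-01	4.274390e-02
12.0	2.888069e+00	1.911317e-01	3.800654e-02
13.0	2.250438e+00	1.904399e-01	3.411367e-02
14.0	1.786320e+00	1.897547e-01	3.086584e-02
15.0	1.440705e+00	1.890760e-01	2.812074e-02
16.0	1.178202e+00	1.884037e-01	2.577431e-02
17.0	9.753538e-01	1.877377e-01	2.374883e-02
18.0	8.161994e-01	1.870779e-01	2.198516e-02
19.0	6.896272e-01	1.864242e-01	2.043757e-02
20.0	5.877425e-01	1.857766e-01	1.907021e-02
21.0	5.048331e-01	1.851350e-01	1.785456e-02
22.0	4.366982e-01	1.844993e-01	1.676772e-02
23.0	3.802019e-01	1.838694e-01	1.579107e-02
24.0	3.329725e-01	1.832452e-01	1.490933e-02
25.0	2.931935e-01	1.826267e-01	1.410990e-02
26.0	2.594584e-01	1.820137e-01	1.338222e-02
27.0	2.306667e-01	1.814062e-01	1.271747e-02
28.0	2.059491e-01	1.808042e-01	1.210815e-02
29.0	1.846132e-01	1.802075e-01	1.154791e-02
30.0	1.661023e-01	1.796161e-01	1.103130e-02
31.0	1.499662e-01	1.790299e-01	1.055362e-02
32.0	1.358378e-01	1.784489e-01	1.011083e-02
33.0	1.234156e-01	1.778729e-01	9.699407e-03
34.0	1.124509e-01	1.773020e-01	9.316270e-03
35.0	1.027371e-01	1.767359e-01	8.958728e-03
36.0	9.410160e-02	1.761748e-01	8.624411e-03
37.0	8.639956e-02	1.756185e-01	8.311226e-03
38.0	7.950879e-02	1.750669e-01	8.017320e-03
39.0	7.332573e-02	1.745201e-01	7.741043e-03
40.0	6.776225e-02	1.739778e-01	7.480926e-03
41.0	6.274303e-02	1.734402e-01	7.235654e-03
42.0	5.820343e-02	1.729070e-01	7.004048e-03
43.0	5.408779e-02	1.723784e-01	6.785048e-03
44.0	5.034799e-02	1.718541e-01	6.577698e-03
45.0	4.694230e-02	1.713342e-01	6.381133e-03
46.0	4.383440e-02	1.708185e-01	6.194572e-03
47.0	4.099262e-02	1.703071e-01	6.017304e-03
48.0	3.838921e-02	1.697999e-01	5.848684e-03
49.0	3.599981e-02	1.692968e-01	5.688121e-03
50.0	3.380299e-02	1.687979e-01	5.535078e-03
51.0	3.177983e-02	1.683029e-01	5.389063e-03
52.0	2.991359e-02	1.678119e-01	5.249624e-03
53.0	2.818942e-02	1.673249e-01	5.116347e-03
54.0	2.659412e-02	1.668418e-01	4.988852e-03
55.0	2.511594e-02	1.663625e-01	4.866786e-03
56.0	2.374438e-02	1.658869e-01	4.749827e-03
57.0	2.247003e-02	1.654152e-01	4.637676e-03
58.0	2.128450e-02	1.649471e-01	4.530054e-03
59.0	2.018020e-02	1.644827e-01	4.426706e-03
60.0	1.915034e-02	1.640219e-01	4.327395e-03
61.0	1.818878e-02	1.635647e-01	4.231898e-03
62.0	1.728997e-02	1.631111e-01	4.140011e-03
63.0	1.644891e-02	1.626609e-01	4.051541e-03
64.0	1.566106e-02	1.622141e-01	3.966312e-03
65.0	1.492230e-02	1.617708e-01	3.884155e-03
66.0	1.422888e-02	1.613308e-01	3.804916e-03
67.0	1.357740e-02	1.608942e-01	3.728449e-03
68.0	1.296474e-02	1.604609e-01	3.654618e-03
69.0	1.238807e-02	1.600308e-01	3.583294e-03
70.0	1.184481e-02	1.596039e-01	3.514360e-03
71.0	1.133258e-02	1.591802e-01	3.447701e-03
72.0	1.084920e-02	1.587597e-01	3.383213e-03
73.0	1.039269e-02	1.583422e-01	3.320795e-03
74.0	9.961215e-03	1.579278e-01	3.260356e-03
75.0	9.553088e-03	1.575165e-01	3.201805e-03
76.0	9.166760e-03	1.571082e-01	3.145061e-03
77.0	8.800804e-03	1.567028e-01	3.090045e-03
78.0	8.453901e-03	1.563004e-01	3.036682e-03
79.0	8.124833e-03	1.559008e-01	2.984904e-03
80.0	7.812474e-03	1.555042e-01	2.934643e-03
81.0	7.515784e-03	1.551104e-01	2.885837e-03
82.0	7.233796e-03	1.547194e-01	2.838427e-03
83.0	6.965617e-03	1.543311e-01	2.792356e-03
84.0	6.710415e-03	1.539456e-01	2.747571e-03
85.0	6.467419e-03	1.535629e-01	2.704023e-03
86.0	6.235913e-03	1.531828e-01	2.661661e-03
87.0	6.015227e-03	1.528053e-01	2.620442e-03
88.0	5.804742e-03	1.524305e-01	2.580321e-03
89.0	5.603876e-03	1.520583e-01	2.541258e-03
90.0	5.412091e-03	1.516887e-01	2.503212e-03
91.0	5.228881e-03	1.513216e-01	2.466147e-03
92.0	5.053774e-03	1.509571e-01	2.430028e-03
93.0	4.886331e-03	1.505950e-01	2.394819e-03
94.0	4.726139e-03	1.502354e-01	2.360488e-03
95.0	4.572810e-03	1.498782e-01	2.327006e-03
96.0	4.425985e-03	1.495234e-01	2.294341e-03
97.0	4.285323e-03	1.491711e-01	2.262467e-03
98.0	4.150505e-03	1.488210e-01	2.231355e-03
99.0	4.021234e-03	1.484734e-01	2.200981e-03
100.0	3.897229e-03	1.481280e-01	2.171319e-03
101.0	3.778225e-03	1.477849e-01	2.142346e-03
102.0	3.663974e-03	1.474441e-01	2.114040e-03
103.0	3.554242e-03	1.471056e-01	2.086378e-03
104.0	3.448810e-03	1.467692e-01	2.059340e-03
105.0	3.347470e-03	1.464351e-01	2.032906e-03
106.0	3.250026e-03	1.461031e-01	2.007058e-03
107.0	3.156295e-03	1.457733e-01	1.981776e-03
108.0	3.066101e-03	1.454456e-01	1.957043e-03
109.0	2.979280e-03	1.451200e-01	1.932843e-03
110.0	2.895678e-03	1.447965e-01	1.909159e-03
111.0	2.815146e-03	1.444751e-01	1.885976e-03
112.0	2.737547e-03	1.441557e-01	1.863278e-03
113.0	2.662748e-03	1.438383e-01	1.841052e-03
114.0	2.590625e-03	1.435230e-01	1.819283e-03
115.0	2.521060e-03	1.432096e-01	1.797958e-03
116.0	2.453941e-03	1.428982e-01	1.777065e-03
117.0	2.389163e-03	1.425887e-01	1.756590e-03
118.0	2.326624e-03	1.422812e-01	1.736523e-03
119.0	2.266230e-03	1.419756e-01	1.716852e-03
120.0	2.207889e-03	1.416718e-01	1.697565e-03
121.0	2.151516e-03	1.413700e-01	1.678652e-03
122.0	2.097028e-03	1.410700e-01	1.660103e-03
123.0	2.044348e-03	1.407718e-01	1.641908e-03
124.0	1.993403e-03	1.404754e-01	1.624057e-03
125.0	1.944121e-03	1.401809e-01	1.606542e-03
126.0	1.896435e-03	1.398881e-01	1.589352e-03
127.0	1.850283e-03	1.395971e-01	1.572480e-03
128.0	1.805602e-03	1.393078e-01	1.555918e-03
129.0	1.762336e-03	1.390203e-01	1.539657e-03
130.0	1.720428e-03	1.387345e-01	1.523689e-03
131.0	1.679827e-03	1.384504e-01	1.508008e-03
132.0	1.640482e-03	1.381679e-01	1.492605e-03
133.0	1.602345e-03	1.378872e-01	1.477474e-03
134.0	1.565371e-03	1.376080e-01	1.462608e-03
135.0	1.529515e-03	1.373306e-01	1.448001e-03
136.0	1.494736e-03	1.370547e-01	1.433646e-03
137.0	1.460994e-03	1.367805e-01	1.419536e-03
138.0	1.428251e-03	1.365078e-01	1.405667e-03
139.0	1.396470e-03	1.362367e-01	1.392031e-03
140.0	1.365617e-03	1.359672e-01	1.378625e-03
141.0	1.335657e-03	1.356992e-01	1.365441e-03
142.0	1.306560e-03	1.354328e-01	1.352476e-03
143.0	1.278294e-03	1.351679e-01	1.339723e-03
144.0	1.250831e-03	1.349045e-01	1.327178e-03
145.0	1.224141e-03	1.346425e-01	1.314836e-03
146.0	1.198199e-03	1.343821e-01	1.302693e-03
147.0	1.172977e-03	1.341231e-01	1.290743e-03
148.0	1.148453e-03	1.338656e-01	1.278983e-03
149.0	1.124601e-03	1.336095e-01	1.267408e-03
150.0	1.101399e-03	1.333548e-01	1.256015e-03
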