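# columns: name density_g_cm3 composition
water	1	H:0.111898,O:0.888102
air	0.0012047	C:0.000124,N:0.755267,O:0.231781,Ar:0.012827
aluminium	2.699	Al:1.000000
iron	7.874	Fe:1.000000
pmma	1.19	H:0.080538,C:0.599848,O:0.319614
concrete	2.3	H:0.022100,C:0.002484,O:0.574930,Na:0.015208,Mg:0.001266,Al:0.019953,Si:0.304627,K:0.010045,Ca:0.042951,Fe:0.006435
carbon_table	0.55	H:0.030000,C:0.910000,O:0.060000
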