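Label	Area	Mean	Circ.	Mean_boundary	StdDev_boundary	Mean_distance
0005-0074:1	6327.373	1903.1	0.86	1529.336	45.033	27.58
0005-0074:2	6327.373	3213.77	0.86	195.313	9.079	27.58
0005-0074:3	6327.373	2151.1	0.86	1450.985	90.775	27.58
0005-0074:4	6327.373	1306.7	0.86	2330.437	60.089	27.58
0005-0074:5	6327.373	45.78	0.86	250.67	12.155	27.58
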