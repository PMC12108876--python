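X_mm,Y_mm
0,0
7,0.66
14,1.32
21,2.63
28,7.22
35,8.54
42,9.85
49,11.82
56,14.44
63,19.69
70,23.63
77,24.94
84,28.22
91,31.50
98,33.47
105,35.44
112,37.41
119,38.07
126,38.72
133,40.04
140,39.38
147,37.41
154,34.13
161,30.85
168,26.25
175,17.72
182,13.13
189,9.85
196,0
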