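# Survival times of head & neck cancer patients under radiotherapy (n=58)
value
6.53
7
10.42
14.48
16.1
22.7
34
41.55
42
45.28
49.4
53.62
63
64
83
84
91
108
112
129
133
133
139
140
140
146
149
154
157
160
160
165
146
149
154
157
160
160
165
173
176
218
225
241
248
273
277
297
405
417
420
440
523
583
594
1101
1146
1417
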