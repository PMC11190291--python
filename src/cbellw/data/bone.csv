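# Survival times (days) of acute bone cancer patients (n=73)
value
0.09
0.76
1.81
1.1
3.72
0.72
2.49
1.0
0.53
0.66
31.61
0.6
0.2
1.61
1.88
0.7
1.36
0.43
3.16
1.57
4.93
11.07
1.63
1.39
4.54
3.12
86.01
1.92
0.92
4.04
1.16
2.26
0.2
0.94
1.82
3.99
1.46
2.75
1.38
2.76
1.86
2.68
1.76
0.67
1.29
1.56
2.83
0.71
1.48
2.41
0.66
0.65
2.36
1.29
13.75
0.67
3.7
0.76
3.63
0.68
2.65
0.95
2.3
2.57
0.61
3.93
1.56
1.29
9.94
1.67
1.42
4.18
1.37
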