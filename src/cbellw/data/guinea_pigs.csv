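# Survival times (days/100) of Guinea pigs infected with virulent tubercle bacilli (n=72)
value
0.1
0.33
0.44
0.56
0.59
0.72
0.74
0.77
0.92
0.93
0.96
1.0
1.0
1.02
1.05
1.07
1.07
1.08
1.08
1.08
1.09
1.12
1.13
1.15
1.16
1.2
1.21
1.22
1.22
1.24
1.3
1.34
1.36
1.39
1.44
1.46
1.53
1.59
1.6
1.63
1.63
1.68
1.71
1.72
1.76
1.83
1.95
1.96
1.97
2.02
2.13
2.15
2.16
2.22
2.3
2.31
2.4
2.45
2.51
2.53
2.54
2.54
2.78
2.93
3.27
3.42
3.47
3.61
4.02
4.32
4.58
5.55
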