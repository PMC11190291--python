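# Remission times (months) of bladder cancer patients (n=128)
value
0.08
0.2
0.4
0.5
0.51
0.81
0.9
1.05
1.19
1.26
1.35
1.4
1.46
1.76
2.02
2.02
2.07
2.09
2.23
2.26
2.46
2.54
2.62
2.64
2.69
2.69
2.75
2.83
2.87
3.02
3.25
3.31
3.36
3.36
3.48
3.52
3.57
3.64
3.7
3.82
3.88
4.18
4.23
4.26
4.33
4.34
4.4
4.5
4.51
4.87
4.98
5.06
5.09
5.17
5.32
5.32
5.34
5.41
5.41
5.49
5.62
5.71
5.85
6.25
6.54
6.76
6.93
6.94
6.97
7.09
7.26
7.28
7.32
7.39
7.59
7.62
7.63
7.66
7.87
7.93
8.26
8.37
8.53
8.65
8.66
9.02
9.22
9.47
9.74
10.06
10.34
10.66
10.75
11.25
11.64
11.79
11.98
12.02
12.03
12.07
12.63
13.11
13.29
13.8
14.24
14.76
14.77
14.83
15.96
16.62
17.12
17.14
17.36
18.1
19.13
20.28
21.73
22.69
23.63
25.74
25.82
26.31
32.15
34.26
36.66
43.01
46.12
79.05
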