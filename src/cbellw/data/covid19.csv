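# Daily confirmed COVID-19 death counts (n=89)
value
1
1
2
4
5
1
1
3
6
6
4
1
5
6
6
8
5
7
7
9
9
15
17
11
13
5
14
5
13
9
19
15
11
14
12
11
7
13
10
20
22
21
12
14
9
14
7
16
17
13
21
11
11
8
11
12
15
21
20
18
15
14
21
16
11
28
29
19
14
19
29
34
34
46
46
47
36
38
40
32
39
34
35
36
35
45
62
91
97
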