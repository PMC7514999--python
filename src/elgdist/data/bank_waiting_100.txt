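0.8
0.8
1.3
1.5
1.8
1.9
1.9
2.1
2.6
2.7
2.9
3.1
3.2
3.3
3.5
3.6
4.0
4.1
4.2
4.2
4.3
4.3
4.4
4.4
4.6
4.7
4.7
4.8
4.9
4.9
5.0
5.3
5.5
5.7
5.7
6.1
6.2
6.2
6.2
6.3
6.7
6.9
7.1
7.1
7.1
7.1
7.4
7.6
7.7
8.0
8.2
8.6
8.6
8.6
8.8
8.8
8.9
8.9
9.5
9.6
9.7
9.8
10.7
10.9
11.0
11.0
11.1
11.2
11.2
11.5
11.9
12.4
12.5
12.9
13.0
13.1
13.3
13.6
13.7
13.9
14.1
15.4
15.4
17.3
17.3
18.1
18.2
18.4
18.9
19.0
19.9
20.6
21.3
21.4
21.9
23.0
27.0
31.6
33.1
38.5
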