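# vertex vertex community(- for bridge edges)
0 1 0
0 2 0
0 3 0
1 2 0
1 3 0
1 4 0
2 3 0
2 4 0
3 4 0
5 6 1
5 7 1
5 8 1
6 7 1
6 8 1
6 9 1
7 8 1
7 9 1
8 9 1
10 11 2
10 12 2
10 13 2
11 12 2
11 13 2
11 14 2
12 13 2
12 14 2
13 14 2
4 5 -
9 10 -
14 0 -
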