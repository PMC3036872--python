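haplotype,KW,KS,RS,HZ,LD
1,1,0,0,0,0
2,1,0,0,0,0
3,1,0,0,0,0
4,1,0,0,0,0
5,1,0,0,0,0
6,1,0,0,0,0
7,1,0,0,0,0
8,1,0,0,0,0
9,1,0,0,0,0
10,1,0,0,0,0
11,1,0,0,0,1
12,2,1,0,0,2
13,1,0,0,0,0
14,1,0,0,0,0
15,1,0,0,0,0
16,1,1,0,0,1
17,0,1,0,0,0
18,0,1,0,0,0
19,0,1,0,0,0
20,0,4,0,0,0
21,0,2,0,0,0
22,0,1,0,0,0
23,0,3,0,1,0
24,0,1,0,0,0
25,0,1,0,0,0
26,0,1,0,0,0
27,0,1,0,0,0
28,0,1,1,2,0
29,0,1,0,0,0
30,0,0,1,0,1
31,0,0,1,0,0
32,0,0,1,0,0
33,0,0,1,1,0
34,0,0,1,0,0
35,0,0,1,0,0
36,0,0,1,0,1
37,0,0,1,0,0
38,0,0,1,0,0
39,0,0,1,0,0
40,0,0,1,1,0
41,0,0,1,0,0
42,0,0,1,0,0
43,0,0,2,0,1
44,0,0,1,0,0
45,0,0,0,1,0
46,0,0,0,1,0
47,0,0,0,1,0
48,0,0,0,1,1
49,0,0,0,1,0
50,0,0,0,1,0
51,0,0,0,1,0
52,0,0,0,1,0
53,0,0,0,1,0
54,0,0,0,1,1
55,0,0,0,1,0
56,0,0,0,1,0
57,0,0,0,1,0
58,0,0,0,0,1
59,0,0,0,0,1
60,0,0,0,0,1
61,0,0,0,0,1
62,0,0,0,0,1
63,0,0,0,0,1
64,0,0,0,0,1
65,0,0,0,0,1
66,0,0,0,0,1
67,0,0,0,0,1
68,0,0,0,0,1
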