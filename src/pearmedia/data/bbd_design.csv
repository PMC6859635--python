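medium_id,KNO3,NH4NO3,mesos,minors,BAP,IBA
1,1.25,0.50,1.50,2.25,0.50,0.20
2,2.00,2.00,1.50,0.50,1.75,0.13
3,1.25,0.50,2.50,2.25,0.50,0.13
4,2.00,1.25,0.50,2.25,1.75,0.05
5,2.00,1.25,2.50,2.25,1.75,0.05
6,2.00,1.25,1.50,0.50,3.00,0.13
7,1.25,0.50,1.50,2.25,3.00,0.05
8,1.25,1.25,0.50,4.00,1.75,0.05
9,2.00,1.25,2.50,2.25,1.75,0.20
10,1.25,2.00,1.50,2.25,3.00,0.20
11,1.25,1.25,2.50,4.00,1.75,0.20
12,0.50,0.50,1.50,4.00,1.75,0.13
13,2.00,0.50,1.50,4.00,1.75,0.13
14,1.25,2.00,0.50,2.25,3.00,0.13
15,0.50,1.25,0.50,2.25,1.75,0.05
16,2.00,0.50,1.50,0.50,1.75,0.13
17,1.25,0.50,1.50,2.25,3.00,0.20
18,1.25,1.25,2.50,0.50,1.75,0.20
19,1.25,0.50,1.50,2.25,0.50,0.05
20,1.25,2.00,2.50,2.25,3.00,0.13
21,1.25,0.50,0.50,2.25,0.50,0.13
22,2.00,1.25,0.50,2.25,1.75,0.20
23,1.25,2.00,0.50,2.25,0.50,0.13
24,1.25,0.50,0.50,2.25,3.00,0.13
25,1.25,2.00,1.50,2.25,3.00,0.05
26,0.50,0.50,1.50,0.50,1.75,0.13
27,0.50,1.25,1.50,4.00,0.50,0.13
28,0.50,1.25,2.50,2.25,1.75,0.20
29,2.00,1.25,1.50,4.00,3.00,0.13
30,1.25,1.25,0.50,0.50,1.75,0.20
31,0.50,2.00,1.50,0.50,1.75,0.13
32,1.25,1.25,2.50,0.50,1.75,0.05
33,0.50,1.25,1.50,0.50,3.00,0.13
34,1.25,1.25,2.50,4.00,1.75,0.05
35,2.00,1.25,1.50,4.00,0.50,0.13
36,1.25,1.25,0.50,0.50,1.75,0.05
37,2.00,1.25,1.50,0.50,0.50,0.13
38,1.25,2.00,1.50,2.25,0.50,0.20
39,1.25,2.00,1.50,2.25,0.50,0.05
40,0.50,1.25,2.50,2.25,1.75,0.05
41,2.00,2.00,1.50,4.00,1.75,0.13
42,1.25,0.50,2.50,2.25,3.00,0.13
43,1.25,1.25,0.50,4.00,1.75,0.20
44,0.50,1.25,1.50,4.00,3.00,0.13
45,1.25,2.00,2.50,2.25,0.50,0.13
46,0.50,1.25,0.50,2.25,1.75,0.20
47,0.50,2.00,1.50,4.00,1.75,0.13
48,0.50,1.25,1.50,0.50,0.50,0.13
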