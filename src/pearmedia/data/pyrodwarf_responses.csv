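medium_id,KNO3,NH4NO3,mesos,minors,BAP,IBA,PR,SL,STN,Vitri,QI
1,1.25,0.50,1.50,2.25,0.50,0.20,2.43,5.32,0,5.33,4.68
2,2.00,2.00,1.50,0.50,1.75,0.13,7.45,1.23,40.17,49.64,1.00
3,1.25,0.50,2.50,2.25,0.50,0.13,1.78,4.93,0,6.43,4.45
4,2.00,1.25,0.50,2.25,1.75,0.05,8.98,2.46,37.32,21.97,1.75
5,2.00,1.25,2.50,2.25,1.75,0.05,8.18,2.51,36.09,21.40,1.78
6,2.00,1.25,1.50,0.50,3.00,0.13,5.13,0.96,31.68,30.25,1.50
7,1.25,0.50,1.50,2.25,3.00,0.05,6.33,3.77,0,5.10,4.53
8,1.25,1.25,0.50,4.00,1.75,0.05,10.18,0.81,17.44,23.35,2.80
9,2.00,1.25,2.50,2.25,1.75,0.20,8.50,2.75,37.14,21.48,1.85
10,1.25,2.00,1.50,2.25,3.00,0.20,5.55,3.47,22.51,37.84,1.65
11,1.25,1.25,2.50,4.00,1.75,0.20,9.33,1.58,16.09,23.04,2.80
12,0.50,0.50,1.50,4.00,1.75,0.13,10.73,1.51,10.01,7.43,3.88
13,2.00,0.50,1.50,4.00,1.75,0.13,9.03,1.77,20.20,9.19,3.48
14,1.25,2.00,0.50,2.25,3.00,0.13,6.00,3.15,24.95,39.17,1.45
15,0.50,1.25,0.50,2.25,1.75,0.05,11.73,2.25,10.28,17.69,3.58
16,2.00,0.50,1.50,0.50,1.75,0.13,9.03,2.08,19.11,12.96,3.30
17,1.25,0.50,1.50,2.25,3.00,0.20,6.35,4.25,0,5.88,4.43
18,1.25,1.25,2.50,0.50,1.75,0.20,9.18,1.85,14.36,28.47,2.58
19,1.25,0.50,1.50,2.25,0.50,0.05,2.23,4.81,0,4.86,4.60
20,1.25,2.00,2.50,2.25,3.00,0.13,5.10,3.15,24.02,38.25,2.68
21,1.25,0.50,0.50,2.25,0.50,0.13,3.08,4.63,3.99,6.76,4.23
22,2.00,1.25,0.50,2.25,1.75,0.20,9.15,2.85,38.00,22.15,1.68
23,1.25,2.00,0.50,2.25,0.50,0.13,2.10,3.07,25.16,38.29,1.53
24,1.25,0.50,0.50,2.25,3.00,0.13,7.03,3.54,5.04,7.05,4.13
25,1.25,2.00,1.50,2.25,3.00,0.05,5.38,3.10,20.51,38.11,1.70
26,0.50,0.50,1.50,0.50,1.75,0.13,10.55,1.83,9.27,10.18,3.83
27,0.50,1.25,1.50,4.00,0.50,0.13,1.80,1.34,8.45,19.23,3.35
28,0.50,1.25,2.50,2.25,1.75,0.20,9.80,2.44,10.46,17.34,3.45
29,2.00,1.25,1.50,4.00,3.00,0.13,4.80,0.91,34.91,23.90,1.75
30,1.25,1.25,0.50,0.50,1.75,0.20,10.08,1.36,17.41,29.10,2.28
31,0.50,2.00,1.50,0.50,1.75,0.13,9.40,0.99,13.11,45.71,1.45
32,1.25,1.25,2.50,0.50,1.75,0.05,9.13,1.53,14.78,28.22,2.53
33,0.50,1.25,1.50,0.50,3.00,0.13,5.75,1.25,7.40,25.21,3.13
34,1.25,1.25,2.50,4.00,1.75,0.05,9.23,1.32,14.09,22.74,2.70
35,2.00,1.25,1.50,4.00,0.50,0.13,1.15,1.32,35.00,23.00,1.65
36,1.25,1.25,0.50,0.50,1.75,0.05,9.95,1.12,16.58,28.65,2.38
37,2.00,1.25,1.50,0.50,0.50,0.13,1.00,1.55,32.50,30.00,1.78
38,1.25,2.00,1.50,2.25,0.50,0.20,1.20,3.14,23.00,36.50,1.70
39,1.25,2.00,1.50,2.25,0.50,0.05,1.03,2.95,19.50,36.50,1.80
40,0.50,1.25,2.50,2.25,1.75,0.05,9.75,2.04,9.23,17.16,3.50
41,2.00,2.00,1.50,4.00,1.75,0.13,7.78,1.04,41.00,43.23,1.00
42,1.25,0.50,2.50,2.25,3.00,0.13,5.60,3.84,0,6.72,4.45
43,1.25,1.25,0.50,4.00,1.75,0.20,10.38,1.06,19.04,23.13,2.65
44,0.50,1.25,1.50,4.00,3.00,0.13,5.83,0.84,8.60,19.72,3.28
45,1.25,2.00,2.50,2.25,0.50,0.13,1.00,3.23,25.00,37.50,1.63
46,0.50,1.25,0.50,2.25,1.75,0.20,12.08,2.25,12.00,17.80,3.48
47,0.50,2.00,1.50,4.00,1.75,0.13,9.50,0.76,15.56,40.25,1.63
48,0.50,1.25,1.50,0.50,0.50,0.13,1.63,1.64,7.20,26.07,2.95
MS,1.00,1.00,1.00,1.00,2.50,0.20,3.53,3.99,14.23,10.23,3.60
WPM,1.00,1.00,1.00,1.00,2.50,0.20,2.28,2.57,6.47,3.25,4.18
QL,1.00,1.00,1.00,1.00,2.50,0.20,2.95,2.62,2.73,0,4.78
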