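entry,atom_type,neighbours,contribution,occurrences,molecules
1,Const,,24.34,1893,1893
2,B,C3,-4.5,1,1
3,B,O3,0.6,6,6
4,B(-),C4,17.49,5,5
5,B(-),CF3,1.11,5,5
6,B(-),F4,1.67,10,10
7,C sp3,H3B(-),1.21,1,1
8,C sp3,H3C,-2.28,3048,1529
9,C sp3,H3C(+),29.45,3,3
10,C sp3,H3N,7.1,111,104
11,C sp3,H3N(+),8.27,34,23
12,C sp3,H3O,3.14,194,155
13,C sp3,H3S,4.71,13,11
14,C sp3,H3S(+),4.66,1,1
15,C sp3,H3P,5.46,2,2
16,C sp3,H3Si,-0.65,113,18
17,C sp3,H2BC,2.28,3,1
18,C sp3,H2BC(-),-6.78,3,3
19,C sp3,H2C2,0.2,6359,1366
20,C sp3,H2C2(+),2.04,7,7
21,C sp3,H2CN,6.38,271,175
22,C sp3,H2CN(+),6.13,74,46
23,C sp3,H2CO,2.92,1277,673
24,C sp3,H2CP,7.04,16,15
25,C sp3,H2CP(+),2.87,24,6
26,C sp3,H2CS,4.57,76,55
27,C sp3,H2CS(+),6.64,5,2
28,C sp3,H2CSi,3.91,12,5
29,C sp3,H2CF,-1.65,5,5
30,C sp3,H2CCl,4.93,51,39
31,C sp3,H2CBr,6.41,41,33
32,C sp3,H2CJ,9.03,28,21
33,C sp3,H2O2,6.18,7,7
34,C sp3,HC3,1.56,428,304
35,C sp3,HC2N,7.61,15,12
36,C sp3,HC2N(+),8.4,6,6
37,C sp3,HC2O,5.08,150,116
38,C sp3,HC2S,5.65,8,5
39,C sp3,HC2Cl,4.68,12,12
40,C sp3,HC2Br,6.37,10,10
41,C sp3,HC2J,9.46,4,4
42,C sp3,HCO2,7.1,15,13
43,C sp3,HCF2,-1.62,29,17
44,C sp3,HCCl2,5.35,12,11
45,C sp3,HCBr2,12.05,3,2
46,C sp3,HO3,9.87,3,3
47,C sp3,C4,3.1,111,104
48,C sp3,C3N,4.53,2,2
49,C sp3,C3O,6.42,36,36
50,C sp3,C3S,4.75,3,3
51,C sp3,C3F,2.23,21,11
52,C sp3,C3Cl,7.32,42,33
53,C sp3,C3Br,3.73,1,1
54,C sp3,C2F2,-0.4,333,57
55,C sp3,C2Cl2,-0.14,2,2
56,C sp3,CNF2,8.26,9,3
57,C sp3,COF2,2.99,34,18
58,C sp3,CF3,-4.98,111,49
59,C sp3,CSF2,0.05,2,1
60,C sp3,CF2Cl,-0.7,2,1
61,C sp3,CPF2(-),2.75,33,11
62,C sp3,CFCl2,-0.74,1,1
63,C sp3,CCl3,4.6,10,9
64,C sp3,N3F(+),-4.3,1,1
65,C sp3,SF3,-2.31,110,57
66,C(-) sp3,C3,9.33,3,3
67,C sp2,H2=C,-2.43,78,77
68,C sp2,HB=C(-),2.74,1,1
69,C sp2,HC=C,1,266,174
70,C sp2,HC=O,2.74,13,13
71,C sp2,H=CN,2.75,216,108
72,C sp2,H=CO,0.25,9,9
73,C sp2,H=CS,4.09,32,30
74,C sp2,H=CCl,0.8,5,3
75,C sp2,H=CBr,-1.85,1,1
76,C sp2,HN=O,10.39,2,2
77,C sp2,HO=O,1.28,13,13
78,C sp2,C2=C,3.15,67,56
79,C sp2,C2=N,5.54,35,29
80,C sp2,C2=O,6.2,73,72
81,C sp2,C=CO,1.71,3,3
82,C sp2,C=CS,5.29,25,24
83,C sp2,C=CCl,3.33,9,5
84,C sp2,C=CBr,7.47,3,3
85,C sp2,CN=O,7.25,2,2
86,C sp2,CO=O,2.25,737,528
87,C sp2,CO=O(-),-2.99,23,23
88,C sp2,=COS,7.31,2,2
89,C sp2,C=OCl,7.53,1,1
90,C sp2,C=OBr,11.42,1,1
91,C sp2,=CSCl,7.43,3,2
92,C sp2,=CSBr,10.37,3,2
93,C sp2,=CSJ,15.69,1,1
94,C sp2,=CCl2,2.74,6,4
95,C sp2,NO=O,6.06,7,4
96,C sp2,O2=O,2.64,12,12
97,C sp2,OS=S,9.18,5,5
98,C aromatic,H:C2,1.01,1614,344
99,C aromatic,H:C:N,4.01,106,63
100,C aromatic,H:C:N(+),8.32,33,18
101,C aromatic,H:N2,2.23,1,1
102,C aromatic,:C3,1.65,119,60
103,C aromatic,C:C2,2.25,313,254
104,C aromatic,C:C:N,5.49,21,20
105,C aromatic,C:C:N(+),13.44,3,3
106,C aromatic,:C2N,6.23,19,19
107,C aromatic,:C2N(+),10.03,10,10
108,C aromatic,:C2:N,9.45,1,1
109,C aromatic,:C2O,3.7,32,29
110,C aromatic,:C2S,6.74,9,9
111,C aromatic,:C2Si,3.98,4,3
112,C aromatic,:C2F,-0.4,9,8
113,C aromatic,:C2Cl,3.95,21,17
114,C aromatic,:C2Br,7.09,4,4
115,C aromatic,:C2J,9.69,3,3
116,C(+) aromatic,H:N2,0.96,104,104
117,C(+) aromatic,C:N2,-22.73,10,10
118,C sp,H#C,1.5,24,24
119,C sp,B#N(-),-4.57,20,5
120,C sp,C#C,1.74,56,40
121,C sp,C#N,5.9,63,62
122,C sp,C#N(-),-2.15,9,3
123,C sp,N#N(-),0.69,16,8
124,C sp,#NS,9.65,4,4
125,C sp,=N=S,4.87,4,4
126,C sp,=N=S(-),4.68,7,7
127,N sp3,H2C,-3.52,28,28
128,N sp3,H2C(pi),4.36,6,6
129,N sp3,H2N,0.56,5,5
130,N sp3,HC2,-9.48,20,20
131,N sp3,HC2(pi),-4.7,7,7
132,N sp3,HC2(2pi),5.79,1,1
133,N sp3,HCN(pi),9.39,2,2
134,N sp3,HSi2,-2.29,1,1
135,N sp3,C3,-14.79,18,18
136,N sp3,C3(pi),-11.8,7,7
137,N sp3,C2N,-7.92,4,4
138,N sp3,C2N(pi),0.56,6,6
139,N sp3,C2N(2pi),4.42,2,2
140,N(+) sp3,HC3,-5.95,1,1
141,N(+) sp3,C4,-5.84,21,21
142,N aromatic,HC:C(+),9.3,3,3
143,N aromatic,:C2,-2.38,64,63
144,N aromatic,C2:C(+),0.45,225,114
145,N aromatic,:C:N,7.05,2,1
146,N(+) aromatic,C:C2,-2.46,18,18
147,N sp2,C=C,0,4,4
148,N sp2,=CN,-0.22,12,6
149,N sp2,C=N,-1.94,6,3
150,N sp2,=CO,0.08,23,23
151,N sp2,N=O,-2.47,9,9
152,N sp2,O=O,3.03,3,3
153,N(+) sp2,CO=O(-),1.7,22,20
154,N(+) sp2,O2=O(-),5.7,23,13
155,N(-),C2,-0.36,8,8
156,N(-),S2,-6.68,54,54
157,O,HC,0.58,161,150
158,O,HC(pi),1.07,90,90
159,O,HN(pi),3.2,6,6
160,O,HO,25.77,2,1
161,O,HP,0.31,13,7
162,O,HS,9,3,3
163,O,BC,-1.36,18,6
164,O,C2,-4.02,288,181
165,O,C2(pi),-1,725,561
166,O,C2(2pi),4.81,5,5
167,O,CN(pi),-2.67,16,16
168,O,CN(+)(pi),-0.78,22,12
169,O,CN(2pi),5.88,4,4
170,O,CP,-0.41,168,75
171,O,CP(pi),-3.25,3,1
172,O,CS,1.66,35,23
173,O,CSi,-3.09,23,5
174,O,Si2,1.66,30,9
175,P3,O3,-1.63,20,20
176,P4,HO2=O,2.98,16,16
177,P4,C2O=O(-),-9.24,1,1
178,P4,CO2=O,-2.1,15,15
179,P4,CO2=O(-),0.34,1,1
180,P4,O3=O,3.17,13,13
181,P4,O3=O(-),-6.46,6,6
182,P4,O2=OF,0.52,2,2
183,P4,O2=OCl,5.47,2,2
184,P4,O=OCl2,8.03,2,2
185,P(-),C3F3,-4.02,11,11
186,P(-),F6,-4.92,6,6
187,P(+),C4,0.32,6,6
188,S2,HC,-1.34,11,11
189,S2,HC(pi),2.89,1,1
190,S2,C2,-2.44,20,20
191,S2,C2(pi),-3.02,15,15
192,S2,C2(2pi),-3.49,33,33
193,S2,CS,0.42,20,12
194,S4,C2=O,5.9,3,3
195,S4,CN=O2(-),0.07,108,54
196,S4,CO=O2,9.34,3,3
197,S4,CO=O2(-),-5.01,5,5
198,S4,C=O2F,1.52,1,1
199,S4,C=O2Cl,7.24,5,5
200,S4,O2=O,-0.65,8,8
201,S4,O2=O2,3.42,4,4
202,S4,O2=O2(-),-6.44,7,7
203,S4,O=O2S,-0.4,4,4
204,S(+),C3,8.96,2,2
205,Si,HC3,-8.53,1,1
206,Si,HC2Cl,-5.31,1,1
207,Si,HCCl2,-4.27,1,1
208,Si,HO3,4.24,1,1
209,Si,C4,-7.91,4,4
210,Si,C3N,0,2,1
211,Si,C3O,-3.02,14,7
212,Si,C3Cl,-4.63,1,1
213,Si,C3Br,-2.81,3,3
214,Si,C2O2,-0.04,21,6
215,Si,C2Cl2,-2.94,1,1
216,Si,C2Br2,1.98,1,1
217,Si,CCl3,-3.39,1,1
218,Si,O4,7.84,6,4
219,(COH)n,COH groups: n > 1,3.26,11,10
220,Alkane,No of C atoms,0.22,1263,125
221,Unsaturated HC,No of C atoms,0.02,1314,125
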