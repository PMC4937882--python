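m,B_bar,omega,n
2,2.395,0.6127,10
3,1.290,0.3839,10
5,1.048,0.2542,10
10,1.030,0.1660,10
15,0.876,0.1100,10
20,0.979,0.1011,10
25,1.085,0.1079,10
30,1.084,0.0835,10
35,0.912,0.0612,10
40,1.033,0.0666,10
60,0.864,0.0342,10
80,0.964,0.0420,10
100,1.024,0.0311,10
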