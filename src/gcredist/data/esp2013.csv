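age_lo,weight
0,5000
5,5500
10,5500
15,5500
20,6000
25,6000
30,6500
35,7000
40,7000
45,7000
50,7000
55,6500
60,6000
65,5500
70,5000
75,4000
80,2500
85,1500
90,800
95,200
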