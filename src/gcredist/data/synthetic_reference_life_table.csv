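age,residual_expectancy
0,88.9
1,88.0
5,84.0
10,79.1
15,74.1
20,69.2
25,64.3
30,59.4
35,54.5
40,49.6
45,44.8
50,40.0
55,35.3
60,30.7
65,26.1
70,21.6
75,17.1
80,12.9
85,9.3
90,6.9
95,5.9
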