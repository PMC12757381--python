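t,S,C,D0,D1
0,906,0,0,0
10,932,0,0,0
20,958,0,1,0
30,878,0,3,0
40,845,22,10,0
50,794,82,33,5
60,677,143,55,24
70,499,221,153,67
80,233,116,288,249
90,59,20,445,380
100,3,1,488,410
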