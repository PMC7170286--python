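checker,pre_n,pre_mean,pre_median,with_n,with_mean,with_median
A,28,48,40,29,30.7,25
B,22,60.3,51,22,43,41.5
C,19,42.1,40,20,38.25,35
D,13,50.5,45,32,38.2,35
E,21,64.3,60,15,54.6,52.5
F,30,36.9,37.5,22,26,21
G,2,39,39,14,36.1,31.5
H,24,48.3,45,17,50,39
I,28,58.2,60,7,42.9,45
J,0,,,8,40.6,30.5
Overall,187,49.4,45,186,39.3,35
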