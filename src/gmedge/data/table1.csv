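pair,std,gmedge
A-B,0.733,0.887
A-C,0.696,0.863
A-D,0.698,0.834
A-E,0.698,0.802
B-C,0.722,0.841
B-D,0.663,0.793
B-E,0.710,0.770
C-D,0.631,0.781
C-E,0.674,0.757
D-E,0.680,0.755
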