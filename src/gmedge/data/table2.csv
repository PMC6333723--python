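pair,std,gmedge
A-B,0.833,0.933
A-C,0.767,0.933
A-D,0.833,0.966
A-E,0.800,0.933
B-C,0.800,0.932
B-D,0.933,0.933
B-E,0.865,0.899
C-D,0.800,0.933
C-E,0.733,0.899
D-E,0.865,0.933
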