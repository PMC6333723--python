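concordance,std,gmedge
5/5 positive,47,51
4/5 positive,5,4
3/5 positive,3,1
3/5 negative,4,0
4/5 negative,11,5
5/5 negative,50,58
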