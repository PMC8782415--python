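tip_pattern,class
B_,B
CD_,CD
AGL6_,AGL6
E_,E
A_,A
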