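,c1,c2,c3,c4
c1,1,0.5,0.3333333333,0.25
c2,2,1,0.6666666667,0.5
c3,3,1.5,1,0.75
c4,4,2,1.333333333,1
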