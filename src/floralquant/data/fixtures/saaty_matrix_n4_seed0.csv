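,c1,c2,c3,c4
c1,1,7,3,1
c2,0.1428571429,1,0.2,0.25
c3,0.3333333333,5,1,0.1111111111
c4,1,4,9,1
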