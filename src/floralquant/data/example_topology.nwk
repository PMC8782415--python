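((B_PI_like,B_AP3_like),((CD_AG_like,CD_STK_like),((AGL6_like_1,AGL6_like_2),(E_SEP_like_1,E_SEP_like_2),(A_AP1_like,A_FUL_like))));
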