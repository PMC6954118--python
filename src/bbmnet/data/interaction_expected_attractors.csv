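syn,deg,fwd,rev,a0,b0,ab,exp_a0,exp_b0,exp_ab
0,0,0,0,0,0,0,0,0,0
0,0,0,0,0,0,1,0,0,1
0,0,0,0,0,1,0,0,1,0
0,0,0,0,0,1,1,0,1,1
0,0,0,0,1,0,0,1,0,0
0,0,0,0,1,0,1,1,0,1
0,0,0,0,1,1,0,1,1,0
0,0,0,0,1,1,1,1,1,1
0,0,0,1,0,0,0,0,0,0
0,0,0,1,0,0,1,1,1,0
0,0,0,1,0,1,0,0,1,0
0,0,0,1,0,1,1,1,1,0
0,0,0,1,1,0,0,1,0,0
0,0,0,1,1,0,1,1,1,0
0,0,0,1,1,1,0,1,1,0
0,0,0,1,1,1,1,1,1,0
0,0,1,0,0,0,0,0,0,0
0,0,1,0,0,0,1,0,0,1
0,0,1,0,0,1,0,0,1,0
0,0,1,0,0,1,1,0,1,1
0,0,1,0,1,0,0,1,0,0
0,0,1,0,1,0,1,1,0,1
0,0,1,0,1,1,0,0,0,1
0,0,1,0,1,1,1,0,0,1
0,0,1,1,0,0,0,0,0,0
0,0,1,1,0,0,1,1,1,1
0,0,1,1,0,1,0,0,1,0
0,0,1,1,0,1,1,1,1,1
0,0,1,1,1,0,0,1,0,0
0,0,1,1,1,0,1,1,1,1
0,0,1,1,1,1,0,1,1,1
0,0,1,1,1,1,1,1,1,1
0,1,0,0,0,0,0,0,0,0
0,1,0,0,0,0,1,0,1,0
0,1,0,0,0,1,0,0,1,0
0,1,0,0,0,1,1,0,1,0
0,1,0,0,1,0,0,0,0,0
0,1,0,0,1,0,1,0,1,0
0,1,0,0,1,1,0,0,1,0
0,1,0,0,1,1,1,0,1,0
0,1,0,1,0,0,0,0,0,0
0,1,0,1,0,0,1,0,1,0
0,1,0,1,0,1,0,0,1,0
0,1,0,1,0,1,1,0,1,0
0,1,0,1,1,0,0,0,0,0
0,1,0,1,1,0,1,0,1,0
0,1,0,1,1,1,0,0,1,0
0,1,0,1,1,1,1,0,1,0
0,1,1,0,0,0,0,0,0,0
0,1,1,0,0,0,1,0,1,0
0,1,1,0,0,1,0,0,1,0
0,1,1,0,0,1,1,0,1,0
0,1,1,0,1,0,0,0,0,0
0,1,1,0,1,0,1,0,1,0
0,1,1,0,1,1,0,0,0,0
0,1,1,0,1,1,1,0,1,0
0,1,1,1,0,0,0,0,0,0
0,1,1,1,0,0,1,0,1,0
0,1,1,1,0,1,0,0,1,0
0,1,1,1,0,1,1,0,1,0
0,1,1,1,1,0,0,0,0,0
0,1,1,1,1,0,1,0,1,0
0,1,1,1,1,1,0,0,0,0
0,1,1,1,1,1,1,0,1,0
1,0,0,0,0,0,0,1,0,0
1,0,0,0,0,0,1,1,0,1
1,0,0,0,0,1,0,1,1,0
1,0,0,0,0,1,1,1,1,1
1,0,0,0,1,0,0,1,0,0
1,0,0,0,1,0,1,1,0,1
1,0,0,0,1,1,0,1,1,0
1,0,0,0,1,1,1,1,1,1
1,0,0,1,0,0,0,1,0,0
1,0,0,1,0,0,1,1,1,0
1,0,0,1,0,1,0,1,1,0
1,0,0,1,0,1,1,1,1,0
1,0,0,1,1,0,0,1,0,0
1,0,0,1,1,0,1,1,1,0
1,0,0,1,1,1,0,1,1,0
1,0,0,1,1,1,1,1,1,0
1,0,1,0,0,0,0,1,0,0
1,0,1,0,0,0,1,1,0,1
1,0,1,0,0,1,0,1,0,1
1,0,1,0,0,1,1,1,0,1
1,0,1,0,1,0,0,1,0,0
1,0,1,0,1,0,1,1,0,1
1,0,1,0,1,1,0,1,0,1
1,0,1,0,1,1,1,1,0,1
1,0,1,1,0,0,0,1,0,0
1,0,1,1,0,0,1,1,1,1
1,0,1,1,0,1,0,1,1,1
1,0,1,1,0,1,1,1,1,1
1,0,1,1,1,0,0,1,0,0
1,0,1,1,1,0,1,1,1,1
1,0,1,1,1,1,0,1,1,1
1,0,1,1,1,1,1,1,1,1
1,1,0,0,0,0,0,1,0,0
1,1,0,0,0,0,1,1,1,0
1,1,0,0,0,1,0,1,1,0
1,1,0,0,0,1,1,1,1,0
1,1,0,0,1,0,0,1,0,0
1,1,0,0,1,0,1,1,1,0
1,1,0,0,1,1,0,1,1,0
1,1,0,0,1,1,1,1,1,0
1,1,0,1,0,0,0,1,0,0
1,1,0,1,0,0,1,1,1,0
1,1,0,1,0,1,0,1,1,0
1,1,0,1,0,1,1,1,1,0
1,1,0,1,1,0,0,1,0,0
1,1,0,1,1,0,1,1,1,0
1,1,0,1,1,1,0,1,1,0
1,1,0,1,1,1,1,1,1,0
1,1,1,0,0,0,0,1,0,0
1,1,1,0,0,0,1,1,1,1
1,1,1,0,0,1,0,1,1,1
1,1,1,0,0,1,1,1,1,1
1,1,1,0,1,0,0,1,0,0
1,1,1,0,1,0,1,1,1,1
1,1,1,0,1,1,0,1,1,1
1,1,1,0,1,1,1,1,1,1
1,1,1,1,0,0,0,1,0,0
1,1,1,1,0,0,1,1,1,1
1,1,1,1,0,1,0,1,1,1
1,1,1,1,0,1,1,1,1,1
1,1,1,1,1,0,0,1,0,0
1,1,1,1,1,0,1,1,1,1
1,1,1,1,1,1,0,1,1,1
1,1,1,1,1,1,1,1,1,1
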