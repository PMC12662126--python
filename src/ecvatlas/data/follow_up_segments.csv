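participant,ct_segments,lge_segments,concordance,edema_segments
1,7,6,partial,2
3,8,6,partial,1
8,10,10,total,0
11,5,5,total,0
12,7,7,total,0
13,2,2,total,0
14,10,10,total,0
15,2,2,total,0
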