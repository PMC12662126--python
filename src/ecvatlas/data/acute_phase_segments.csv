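participant,ct_segments,lge_segments,concordance,edema_segments
1,13,12,partial,4
2,8,6,partial,4
3,19,6,partial,10
4,13,10,partial,6
5,1,1,total,1
6,7,5,partial,4
7,13,13,total,0
9,12,12,total,2
10,10,10,total,5
11,16,2,partial,2
12,7,7,total,2
13,2,2,total,1
14,9,9,total,4
15,6,6,total,3
16,3,3,total,0
17,6,6,total,3
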