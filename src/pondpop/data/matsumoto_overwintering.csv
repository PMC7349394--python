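site_id,autumn_count,spring_count
3,10,1
5,2,0
6,21,2
7,10,0
9,28,10
11,34,2
13,0,0
14,0,0
16,80,27
21,20,11
22,22,7
23,1,0
24,24,10
27,0,0
28,0,0
31,44,1
32,4,0
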