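subject_id,sex,age,stroke_type,affected_hemisphere,stroke_duration_days,barthel,fma_ue_t1,fma_ue_t2,fma_d_t1,fma_d_t2,fma_p_t1,fma_p_t2
1,F,59,infarction,L,95,90,17,,,,,
2,M,47,infarction,L,26,90,54,,,,,
3,M,69,infarction,L,178,25,6,,,,,
4,M,66,infarction,L,47,45,10,,,,,
5,M,66,infarction,L,81,45,12,,,,,
6,M,77,infarction,L,441,55,41,,,,,
7,M,66,infarction,L,165,40,4,,,,,
8,F,72,infarction,L,32,45,37,,,,,
9,M,38,infarction,L,10,95,64,,,,,
10,F,76,infarction,L,209,75,10,,,,,
11,M,66,infarction,R,62,40,25,,,,,
12,M,66,infarction,R,96,40,27,,,,,
13,M,66,infarction,R,80,45,32,,,,,
14,F,66,infarction,R,35,40,0,,,,,
15,M,57,infarction,R,16,40,0,,,,,
16,M,48,hemorrhage,R,68,55,6,,,,,
17,M,78,infarction,R,59,90,44,,,,,
18,M,64,infarction,R,68,30,6,,,,,
19,F,61,infarction,R,9,35,8,,,,,
20,F,74,infarction,R,101,65,35,,,,,
21,F,79,infarction,L,102,30,16,,,,,
22,M,73,infarction,L,153,60,15,,,,,
23,M,61,infarction,L,182,45,26,,,,,
24,M,66,infarction,R,177,60,21,,,,,
25,M,42,hemorrhage,L,29,45,0,,,,,
26,M,73,infarction,L,32,60,19,,,,,
27,F,72,hemorrhage,R,88,45,9,,,,,
28,M,72,infarction,R,20,65,40,,,,,
29,M,72,hemorrhage,R,224,55,40,,,,,
30,F,65,infarction,R,51,70,22,,,,,
31,M,71,hemorrhage,R,63,60,36,,,,,
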