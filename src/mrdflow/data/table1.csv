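patient_id,n_post_cht,n_post_venhma,n_post_allosct,n_total,n_laip,aml_pct,CD34,CD117,CD33,CD13,HLA-DR,CD4,CD7,CD56,CD25,CD15,CD123
1,2,2,0,4,2,47,10,100,100,100,100,35,0,58,0,38,100
2,8,0,1,9,2,27,100,100,100,77,100,85,0,20,0,0,0
3,2,0,1,3,2,36,0,100,100,100,100,32,0,50,0,0,0
4,3,2,1,6,2,30,5,100,100,85,100,60,0,24,0,0,100
5,2,5,0,7,3,57,2,100,100,100,100,10,64,38,53,50,0
6,3,1,0,4,2,14,50,100,100,100,100,55,0,25,0,0,0
7,6,0,1,7,2,77,100,80,100,100,100,35,75,0,0,0,0
8,3,3,0,6,3,67,78,100,100,100,70,54,63,0,67,0,80
9,0,5,0,5,2,14,0,100,100,100,100,68,30,0,0,0,0
10,7,0,0,7,2,50,1,100,100,75,90,78,2,21,1,50,0
11,0,6,0,6,2,44,0,100,100,78,100,67,22,0,0,0,0
12,3,1,0,4,2,25,0,100,100,100,100,32,46,0,0,0,0
13,8,0,0,8,2,20,2,100,100,67,100,61,0,30,0,33,100
14,0,7,0,7,2,60,10,100,100,60,100,66,22,0,0,28,80
15,0,2,0,2,2,63,100,100,100,100,100,50,100,0,0,0,0
16,0,5,0,5,2,35,100,100,100,100,100,40,50,0,0,0,0
17,4,3,0,7,2,20,0,100,100,42,100,75,10,20,0,6,100
18,3,3,0,6,3,62,0,100,100,100,100,32,48,21,0,0,0
19,2,0,0,2,2,82,100,100,60,85,100,11,20,50,0,0,0
20,0,4,0,4,2,20,100,100,100,100,100,20,30,0,0,0,0
21,2,2,0,4,2,20,5,100,100,100,100,15,58,0,98,70,100
22,0,2,0,2,2,21,8,100,100,100,100,27,8,37,0,0,0
23,0,2,0,2,2,81,100,100,100,100,100,32,100,0,0,0,0
24,0,3,0,3,3,73,5,100,100,100,100,60,33,0,95,80,0
25,4,0,1,5,2,50,43,100,100,52,58,48,6,0,56,25,0
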