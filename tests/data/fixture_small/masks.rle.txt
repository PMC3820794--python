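#divabc-mask v1
#n_per_species 4 4
>locus_0000 length=200 local_r_mean=7.7887658344126437e-08
2,1,4,1,7,1,6,1,16,1,7,1,24,1,26,1,2,1,3,1,32,1,1,1,2,1,9,1,3,1,1,1,5,1,20,1,12
3,1,12,1,21,2,2,2,14,2,2,1,4,1,8,1,17,1,31,1,2,1,12,1,7,1,8,1,26,1,4,1,8
13,1,6,1,4,1,2,1,7,1,1,1,15,1,21,1,4,2,4,1,21,1,32,1,13,1,23,2,16,1,1
1,1,14,1,1,1,8,1,1,1,11,1,1,2,5,1,6,1,52,1,1,1,10,1,10,1,4,1,1,1,1,1,33,1,5,1,2,1,5,1,5,1,1
1,1,19,1,2,1,7,1,8,1,23,2,20,1,6,2,4,1,9,1,6,1,9,2,3,1,8,1,23,1,2,1,2,1,15,1,12
4,1,8,1,8,1,5,1,26,1,6,1,13,1,1,1,3,2,12,1,35,1,2,1,1,1,24,1,16,1,12,1,4,1,2
10,1,21,1,12,1,4,1,9,1,39,1,3,1,14,1,17,1,14,1,1,1,21,1,3,1,1,1,15,1,1
1,1,2,1,2,1,6,1,4,1,19,1,20,1,16,1,9,1,4,1,29,1,5,1,4,1,26,1,1,1,3,1,17,1,15
>locus_0001 length=200 local_r_mean=3.1315886538690658e-08
14,1,1,1,9,1,31,1,2,1,4,1,18,1,23,1,18,1,18,2,20,1,7,2,1,1,8,1,10
31,2,20,1,12,1,6,1,33,1,12,1,30,1,5,1,5,1,3,1,4,1,2,1,4,1,9,1,2,1,5,1
3,1,5,1,16,1,9,1,8,1,5,1,12,1,2,2,30,2,39,1,2,1,12,1,5,1,10,1,5,1,7,1,9,1,2
5,1,5,1,7,1,7,2,2,1,23,1,17,1,1,1,2,1,6,1,5,1,3,1,1,1,19,1,16,1,9,1,4,1,16,1,5,1,7,1,2,2,4,1,10
7,1,24,2,18,2,9,1,18,1,37,1,3,1,9,1,10,1,18,1,7,1,2,1,10,1,13
4,1,8,1,12,1,2,1,35,1,2,1,8,2,2,1,3,1,1,1,23,1,1,1,19,1,17,1,1,1,5,1,12,2,6,1,9,1,1,1,2,1,4
1,1,14,1,7,1,25,1,1,1,4,2,6,1,2,1,12,1,10,1,4,1,8,1,18,2,10,1,5,1,25,1,7,1,15,1,6
6,1,28,1,6,1,5,1,3,1,5,1,17,1,6,1,1,2,6,1,3,1,1,1,6,1,4,2,8,1,4,1,12,1,6,1,43,1,7,1,1
>locus_0002 length=200 local_r_mean=5.8915004930304362e-08
7,1,7,1,2,1,9,1,18,2,3,1,39,1,2,1,2,1,9,1,6,1,5,1,23,1,1,1,17,1,4,1,23,1,5
8,1,76,1,4,1,17,1,11,1,15,1,15,2,2,1,1,1,6,1,11,1,4,1,4,1,2,1,9
15,1,36,1,28,1,2,1,1,1,2,1,8,1,7,3,17,2,9,2,5,1,2,1,4,1,3,1,5,1,3,1,6,1,4,2,2,1,9,1,7
7,1,2,1,2,1,4,1,13,2,3,1,4,1,1,1,1,2,26,1,14,1,5,2,22,1,2,1,6,1,1,1,3,2,10,1,3,1,1,1,9,1,3,1,2,1,1,1,5,1,21
0,1,2,1,5,2,5,1,10,1,4,2,9,1,15,1,2,1,1,1,11,1,12,1,14,1,14,1,7,1,9,1,12,1,7,1,31,2,8
2,1,39,1,8,1,12,2,9,1,2,1,11,1,6,1,3,2,4,1,18,2,7,1,16,1,2,1,4,1,6,1,9,1,22
16,1,1,1,2,1,7,1,2,1,1,1,7,1,5,1,17,1,6,1,18,1,13,1,7,1,3,1,4,1,19,2,4,1,17,1,3,1,9,1,17,1
23,2,21,1,8,1,12,1,20,2,1,1,3,1,6,1,3,1,27,1,2,1,3,1,3,1,6,1,20,1,15,1,1,1,3,1,3
>locus_0003 length=200 local_r_mean=9.4454103736608408e-08
0,2,23,1,2,1,10,1,13,1,3,1,3,1,18,1,2,1,10,1,14,1,10,1,6,1,1,1,2,3,8,1,16,1,7,1,23,1,2,1,1,1,2
1,2,29,1,5,2,10,2,9,1,30,1,11,1,26,1,1,1,9,1,1,1,35,1,17,1
0,1,1,1,5,1,5,1,6,1,7,2,18,1,3,1,22,1,3,1,9,1,5,1,10,1,1,2,12,1,8,1,2,2,13,1,6,1,21,1,5,1,12,1,1
7,1,1,1,13,2,31,2,3,1,2,1,9,1,4,1,4,1,9,1,5,1,13,1,3,1,15,1,3,1,23,1,1,1,7,1,5,2,8,2,5,1,4
31,1,6,1,40,1,8,1,6,1,36,1,6,1,5,1,3,1,3,2,10,1,6,1,8,1,1,1,5,1,10
11,1,14,1,7,1,8,1,2,1,9,2,1,1,14,1,1,1,9,1,9,1,28,1,11,1,9,1,14,1,10,1,1,1,2,1,1,1,1,1,7,1,5,1,3
2,1,19,1,12,1,20,1,6,1,23,1,1,1,15,1,3,1,1,1,10,1,31,1,8,1,17,1,3,1,14
4,1,12,1,4,1,19,1,4,1,2,1,4,1,1,1,14,1,1,1,12,1,8,1,14,1,4,1,1,1,5,1,11,2,33,1,10,1,2,1,2,1,2,1,8
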