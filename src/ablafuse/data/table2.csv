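treatment,lesion,tumor_type,segment,registration_quality_r1,registration_quality_r2,position_r1,position_r2,clinical_indication_r1,clinical_indication_r2,confidence_r1,confidence_r2
1,1,HCC,6,5,4,5,5,5,5,5,5
2,1,HCC,2,3,3,3,3,3,3,4,5
2,2,HCC,8,,,4,3,4,4,4,5
3,1,HCC,4,4,4,4,5,5,5,5,4
4,1,HCC,2,3,4,4,5,5,5,5,5
5,1,MET,7,5,5,4,5,4,5,5,5
6,1,HCC,2,5,5,5,5,5,5,5,5
7,1,HCC,4,4,5,5,4,5,5,5,5
8,1,HCC,5,5,4,4,5,4,5,5,4
9,1,HCC,5,5,5,5,5,5,5,5,5
10,1,HCC,5,4,5,5,4,5,5,5,5
11,1,MET,8,5,4,5,4,5,5,5,5
12,1,HCC,6,5,4,5,5,4,4,4,5
13,1,MET,4,4,5,4,5,5,5,5,4
14,1,HCC,4,2,3,4,4,4,4,4,3
15,1,MET,2,3,3,3,4,4,3,4,4
16,1,HCC,8,5,4,4,5,4,4,4,4
16,2,HCC,2,,,3,4,3,3,3,4
17,1,HCC,3,5,5,4,5,4,4,4,5
18,1,HCC,5,5,5,5,5,5,5,5,5
18,2,HCC,4,,,5,5,5,5,5,5
19,1,HCC,8,4,5,4,5,5,4,5,5
20,1,HCC,8,5,5,5,5,5,5,5,5
20,2,HCC,4,,,5,5,5,5,5,5
21,1,HCC,5,5,4,4,4,3,3,3,4
22,1,HCC,6,4,4,5,4,5,5,5,4
23,1,HCC,2,5,4,4,5,4,5,4,4
24,1,HCC,4,4,5,5,5,5,5,5,4
24,2,HCC,3,,,5,4,5,5,5,5
25,1,MET,2,5,4,5,5,5,5,5,4
26,1,HCC,2,3,4,5,4,5,4,5,5
27,1,HCC,5,5,5,4,5,4,5,4,5
27,2,HCC,2,,,4,5,4,5,4,5
28,1,MET,7,5,5,4,4,4,4,4,4
28,2,MET,8,,,5,4,5,5,5,5
29,1,MET,8,5,5,5,5,5,5,5,5
29,2,MET,2,,,5,5,5,5,5,5
30,1,MET,2,4,5,5,5,5,5,5,5
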