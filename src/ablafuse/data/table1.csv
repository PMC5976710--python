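treatment,lesion,sex,age,tumor_type,segment,tumor_volume_cm3,ablation_volume_cm3,residual_volume_cm3,residual_percentage
1,1,M,71,HCC,6,0.8,19.1,0,0
2,1,M,81,HCC,8,2.1,47.1,0.03,1.4
2,2,M,81,HCC,2,0.5,5.0,0.5,100
3,1,M,70,HCC,4,3.2,43.7,0.2,6.3
4,1,M,81,HCC,2,0.6,28.2,0.01,1.2
5,1,F,74,MET,7,11.2,39.2,0.2,5.8
6,1,M,75,HCC,2,13.6,18.2,0.6,14.3
7,1,F,80,HCC,4,0.9,3.0,0,0
8,1,M,85,HCC,5,11.7,25.0,3.3,28.3
9,1,M,70,HCC,8,4.8,10.5,0,0
10,1,M,71,HCC,5,1.1,5.3,0,0
11,1,M,76,MET,8,0.5,2.9,0.01,12.8
12,1,M,82,HCC,6,0.5,3.3,0,0
13,1,M,71,MET,4,1.0,5.2,0,0
14,1,M,80,HCC,4,11.1,35.7,1.3,11.5
15,1,F,65,MET,2,1.0,15.4,0.6,58.1
16,1,M,79,HCC,8,1.5,9.7,0,0
16,2,M,79,HCC,2,2.5,9.3,0,0
17,1,M,77,HCC,3,9.4,23.9,0,0
18,1,M,70,HCC,5,1.4,2.9,0,0
18,2,M,70,HCC,4,5.0,10.0,0,0
19,1,F,83,HCC,8,2.8,4.0,0,0
20,1,F,76,HCC,8,0.6,3.7,0,0
20,2,F,76,HCC,4,0.8,5.3,0,0
21,1,M,81,HCC,5,4.7,12.0,0,0
22,1,F,72,HCC,6,5.7,7.6,0.6,10.2
23,1,M,81,HCC,2,6.9,13.0,1.7,24.2
24,1,M,72,HCC,4,14.5,20.9,0,0
24,2,M,72,HCC,3,0.8,4.0,0.8,100
25,1,M,82,MET,2,10.3,22.9,0,0
26,1,M,81,HCC,2,0.4,18.8,0,0
27,1,F,75,HCC,5,2.5,6.6,0,0
27,2,F,75,HCC,2,1.2,7.0,0.4,31.7
28,1,M,78,MET,7,0.8,3.8,0,0
28,2,M,78,MET,8,0.4,2.9,0,0
29,1,F,78,MET,8,2.5,4.0,0,0
29,2,F,78,MET,2,1.1,5.3,0,0
30,1,M,77,MET,2,0.6,3.0,0,0
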