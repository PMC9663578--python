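sample_code,sex,ajcc_stage,sanger_status,double_pos_pct,egfr_pos_pct,hx103_pos_pct,ddpcr_status
1,M,I,19del,37.7,72.7,39.7,
2,M,I,none,62.2,98.9,58.0,none
3,M,II,19del,22.2,93.9,21.9,
4,F,II,L858R,56.2,89.9,56.5,
5,M,I,19del,40.6,85.2,39.0,
6,F,I,19del,60.9,90.5,61.8,
7,F,I,L858R,1.69,11.2,2.40,
8,M,I,none,22.6,21.6,90.6,
9,F,II,none,44.4,59.3,54.6,19del
10,F,II,none,5.35,29.3,13.4,
11,M,II,none,2.39,28.3,4.48,
12,F,I,L858R,98.7,98.9,99.6,
13,M,III,L858R,80.3,98.2,65.7,
14,F,IV,none,0.02,14.7,0.50,
15,F,I,none,0.03,0.26,9.84,
16,F,II,none,0.15,0.78,1.72,
17,F,I,L858R,57.8,64.8,74.7,
18,M,I,none,1.70,2.52,20.1,
19,F,I,none,0.04,5.18,2.48,
20,F,II,L858R,39.8,43.2,50.0,
21,F,II,none,7.26,13.9,22.9,
22,M,I,L858R,59.9,65.1,76.4,
23,F,I,L858R,79.8,79.8,97.5,
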