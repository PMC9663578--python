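patient_no,mutation,first_line_treatment,response,double_pos_pct,egfr_pos_pct,hx103_pos_pct
1,19del,Afatinib,PR,47.7,73.8,48.0
2,19del,Afatinib,PR,46.4,58.2,53.5
3,L858R,Afatinib,SD,26.2,64.5,30.4
4,L858R,Dacomitinib,PR,38.0,48.3,49.5
5,19del,Gefitinib,CR,54.7,69.2,61.9
6,L858R,Dacomitinib,PR,42.6,59.3,48.6
7,L858R,Gefitinib,PR,34.2,35.2,51.5
8,19del,Dacomitinib,PD,4.84,11.2,13.7
9,L858R,Icotinib,NE,50.9,49.8,92.6
10,19del,Icotinib,CR,41.6,48.7,51.0
11,L858R,Icotinib,SD,2.07,0.83,11.8
12,L858R,Erlotinib,NE,30.8,29.8,76.0
13,19del,Gefitinib,PR,55.7,53.9,77.5
14,19del,Gefitinib,PR,30.8,58.9,45.5
15,L858R,Afatinib,SD,4.81,10.0,12.1
16,none,Other,SD,2.61,9.10,5.01
17,none,Other,PR,13.7,39.4,21.9
18,none,Other,PR,4.44,16.9,11.0
19,none,Other,SD,3.27,12.5,7.41
20,none,Other,SD,0.60,10.9,3.16
21,none,None,NE,-0.3,21.3,-1.8
22,none,Other,NE,1.35,-3.51,3.59
23,none,Other,NE,4.89,7.13,12.9
24,none,Other,SD,0.10,1.92,4.01
25,none,Other,NE,0.24,14.5,1.16
26,none,Other,SD,1.08,17.5,7.12
27,none,Other,SD,10.8,24.0,18.4
28,none,None,NE,4.24,2.70,19.5
29,none,Other,PD,2.10,5.06,10.5
30,none,Other,PR,0.45,-3.7,20.6
31,none,Other,PR,6.32,8.10,16.0
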