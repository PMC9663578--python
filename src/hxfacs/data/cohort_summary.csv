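characteristic,category,total,L858R,19del,WT
patients_n,,31,8,7,16
age_years,median,66,66,66,67
age_years,range,49-87,52-86,49-76,53-87
sex,male,21,5,3,4
sex,female,10,3,4,3
stage_ajcc,II,1,0,0,1
stage_ajcc,III,6,0,0,6
stage_ajcc,IV,24,8,7,9
double_pos_pct,ge_30.1,10,5,5,0
double_pos_pct,lt_30.1,21,3,2,16
egfr_tki_therapy,,15,8,7,0
tki_response,CR/PR,9,3,6,
tki_response,SD,3,3,0,
tki_response,PD,1,0,1,
tki_response,NE,2,2,0,
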