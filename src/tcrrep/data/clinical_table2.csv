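patient_id,group,clinical_diagnosis,age_of_onset,lymphocytes,t_cells,cd4,cd8,b_cells
P1,atypical_SCID,Atypical CID,4,4000,1501,825,310,109
P2,atypical_SCID,Atypical CID,15,3600,2120,612,1510,72
P3,atypical_SCID,Atypical CID,1.5,2464,1374,616,665,714
P4,AT,AT,1.5,2250,1720,1030,680,230
P5,AT,AT,2.5,1740,1449,748,609,152
P6,AT,AT,2,1872,1530,820,672,135
P7,AT,AT,1,1680,1390,713,550,107
P8,AT,AT,2,1330,950,520,375,110
P9,AT,AT,0.5,1108,731,509,188,75
P10,ICF1,Atypical CID,1.5,3350,2950,2057,836,114
P11,ICF1,Atypical CID,7,4200,3360,1512,1764,418
P12,ICF1,Atypical CID,4,5400,4025,2590,1677,810
P13,ICF1,Atypical CID,1,1915,1263,574,708,445
P14,ICF1,Atypical CID,10,2280,1478,785,696,547
P15,ICF1,Atypical CID,0.5,2491,1395,822,498,810
P16,ICF2,Atypical CID,5,3700,2845,1950,854,726
P17,ICF2,Atypical CID,22,1557,1022,705,309,250
P18,ICF2,Atypical CID,8,1932,1375,347,985,385
P19,ICF2,Atypical CID,1.5,2950,2440,1180,1093,74
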