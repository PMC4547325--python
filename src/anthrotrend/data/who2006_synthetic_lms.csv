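kind,metric,sex,age_months,L,M,S
WHO2006,height,male,0,1.0,49.9,0.038076
WHO2006,height,male,6,1.0,67.6,0.034024
WHO2006,height,male,12,1.0,75.7,0.035667
WHO2006,height,male,18,1.0,82.3,0.035237
WHO2006,height,male,24,1.0,87.1,0.035591
WHO2006,height,male,30,1.0,91.9,0.036997
WHO2006,height,male,36,1.0,96.1,0.038502
WHO2006,height,male,42,1.0,99.9,0.04004
WHO2006,height,male,48,1.0,103.3,0.040658
WHO2006,height,male,54,1.0,106.7,0.041237
WHO2006,height,male,60,1.0,110.0,0.041818
WHO2006,height,female,0,1.0,49.1,0.038697
WHO2006,height,female,6,1.0,65.7,0.035008
WHO2006,height,female,12,1.0,74.0,0.036486
WHO2006,height,female,18,1.0,80.7,0.037175
WHO2006,height,female,24,1.0,85.7,0.038506
WHO2006,height,female,30,1.0,90.7,0.039691
WHO2006,height,female,36,1.0,95.1,0.041009
WHO2006,height,female,42,1.0,99.0,0.042424
WHO2006,height,female,48,1.0,102.7,0.043817
WHO2006,height,female,54,1.0,106.2,0.043785
WHO2006,height,female,60,1.0,109.4,0.043876
WHO2006,weight,male,0,0.2,3.3,0.125
WHO2006,weight,male,6,0.2,7.9,0.108
WHO2006,weight,male,12,0.2,9.6,0.107
WHO2006,weight,male,18,0.2,10.9,0.108
WHO2006,weight,male,24,0.2,12.2,0.11
WHO2006,weight,male,30,0.2,13.3,0.113
WHO2006,weight,male,36,0.2,14.3,0.116
WHO2006,weight,male,42,0.2,15.3,0.119
WHO2006,weight,male,48,0.2,16.3,0.122
WHO2006,weight,male,54,0.2,17.3,0.1245
WHO2006,weight,male,60,0.2,18.3,0.127
WHO2006,weight,female,0,0.2,3.2,0.13
WHO2006,weight,female,6,0.2,7.3,0.12
WHO2006,weight,female,12,0.2,8.9,0.119
WHO2006,weight,female,18,0.2,10.2,0.121
WHO2006,weight,female,24,0.2,11.5,0.124
WHO2006,weight,female,30,0.2,12.7,0.1265
WHO2006,weight,female,36,0.2,13.9,0.129
WHO2006,weight,female,42,0.2,15.0,0.1315
WHO2006,weight,female,48,0.2,16.1,0.134
WHO2006,weight,female,54,0.2,17.2,0.136
WHO2006,weight,female,60,0.2,18.2,0.1375
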