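kind,metric,sex,age_months,L,M,S
NCHS1977,height,male,0,1.0,50.5,0.041584
NCHS1977,height,male,6,1.0,66.5,0.039098
NCHS1977,height,male,12,1.0,76.0,0.039474
NCHS1977,height,male,18,1.0,82.0,0.040244
NCHS1977,height,male,24,1.0,86.5,0.040462
NCHS1977,height,male,30,1.0,91.2,0.041667
NCHS1977,height,male,36,1.0,95.2,0.043067
NCHS1977,height,male,42,1.0,98.9,0.044489
NCHS1977,height,male,48,1.0,102.4,0.045898
NCHS1977,height,male,54,1.0,105.8,0.046314
NCHS1977,height,male,60,1.0,109.0,0.046789
NCHS1977,height,female,0,1.0,49.9,0.042084
NCHS1977,height,female,6,1.0,65.0,0.04
NCHS1977,height,female,12,1.0,74.3,0.040377
NCHS1977,height,female,18,1.0,80.4,0.041045
NCHS1977,height,female,24,1.0,85.2,0.042254
NCHS1977,height,female,30,1.0,90.0,0.043333
NCHS1977,height,female,36,1.0,94.2,0.044586
NCHS1977,height,female,42,1.0,98.0,0.045918
NCHS1977,height,female,48,1.0,101.6,0.047244
NCHS1977,height,female,54,1.0,105.0,0.047619
NCHS1977,height,female,60,1.0,108.3,0.048015
NCHS1977,weight,male,0,0.0,3.4,0.13
NCHS1977,weight,male,6,0.0,7.8,0.12
NCHS1977,weight,male,12,0.0,10.2,0.115
NCHS1977,weight,male,18,0.0,11.5,0.115
NCHS1977,weight,male,24,0.0,12.6,0.117
NCHS1977,weight,male,30,0.0,13.7,0.12
NCHS1977,weight,male,36,0.0,14.7,0.122
NCHS1977,weight,male,42,0.0,15.7,0.125
NCHS1977,weight,male,48,0.0,16.7,0.128
NCHS1977,weight,male,54,0.0,17.7,0.131
NCHS1977,weight,male,60,0.0,18.7,0.134
NCHS1977,weight,female,0,0.0,3.3,0.135
NCHS1977,weight,female,6,0.0,7.2,0.125
NCHS1977,weight,female,12,0.0,9.5,0.12
NCHS1977,weight,female,18,0.0,10.8,0.12
NCHS1977,weight,female,24,0.0,12.0,0.122
NCHS1977,weight,female,30,0.0,13.0,0.125
NCHS1977,weight,female,36,0.0,14.1,0.127
NCHS1977,weight,female,42,0.0,15.1,0.13
NCHS1977,weight,female,48,0.0,16.0,0.133
NCHS1977,weight,female,54,0.0,17.0,0.136
NCHS1977,weight,female,60,0.0,18.0,0.139
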