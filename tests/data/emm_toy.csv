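,age_group,sex,body_fat,hba1c,pa_total,sampling_time,fasting_time,statins,y
s0,young,female,25.01,4.797,201.3,14,5.87,0,0.286188
s1,young,female,26.79,5.063,211.5,16,7.33,1,0.38396
s2,young,female,23.36,4.63,323.7,14,8.88,1,0.643495
s3,young,female,19.66,4.813,211.5,10,4.65,0,0.332815
s4,young,male,22.27,4.647,258.0,14,6.41,1,0.646758
s5,young,male,19.05,5.129,313.1,12,5.07,1,0.123966
s6,young,male,25.36,4.82,225.0,8,6.25,0,0.801439
s7,young,male,33.04,5.281,253.3,8,3.63,1,0.739009
s8,aged,female,22.05,5.247,266.6,14,4.84,1,1.724064
s9,aged,female,21.28,5.144,263.8,10,5.61,1,1.452144
s10,aged,female,27.94,4.445,186.5,12,7.8,1,1.246728
s11,aged,female,27.14,5.038,264.6,10,8.29,1,1.576991
s12,aged,male,25.63,5.185,341.5,10,3.35,0,1.342665
s13,aged,male,19.42,5.234,167.2,8,4.41,0,1.914463
s14,aged,male,24.82,4.741,311.6,10,7.29,1,1.4937
s15,aged,male,29.17,5.057,267.2,16,2.02,0,1.875091
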