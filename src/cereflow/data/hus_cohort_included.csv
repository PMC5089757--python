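patient_id,sex,age_years,days_symptom_to_mri,mri_signal_code,etco2_mmHg,swi_score,ttp_frames,anesthesia
1,m,55.2,8,7,34,1,9.00,true
2,f,56.4,3,6,31,1,5.17,true
3,f,67.2,9,6,31,1,3.73,true
4,m,32.1,4,7,32,1,8.26,true
5,f,56.2,5,1,28,1,8.22,true
6,f,39.0,6,6,26,1,9.54,true
7,f,21.3,0,1,30,4,8.68,true
8,f,29.8,3,6,39,2,8.07,true
9,m,75.6,7,0,31,3,10.18,true
10,m,12.2,2,6,n/a,1,5.39,false
11,f,10.6,15,0,n/a,3,6.60,false
12,m,5.3,1,6,n/a,1,7.07,true
13,f,25.8,2,6,n/a,1,5.31,false
14,f,20.5,2,6,40,1,6.65,true
16,f,31.9,7,6,29,1,9.00,true
17,f,40.9,0,0,n/a,2,8.43,false
18,m,66.5,2,0,n/a,3,8.94,false
19,f,36.5,5,6,18,2,9.36,true
21,f,22.4,18,0,n/a,2,7.92,false
22,f,41.7,3,6,n/a,2,5.86,false
27,f,65.3,7,0,33,1,8.64,true
28,f,31.1,8,7,n/a,2,8.66,false
31,f,60.9,9,0,n/a,1,9.06,false
32,f,39.3,9,0,n/a,1,8.80,false
34,f,5.4,5,0,n/a,1,7.09,true
37,m,44.2,8,0,n/a,4,8.87,false
38,m,70.0,0,0,n/a,4,9.64,false
39,f,40.7,8,0,n/a,2,7.60,false
41,m,28.5,13,0,n/a,1,7.83,false
42,m,25.3,8,0,n/a,1,7.56,false
43,m,26.1,9,0,n/a,1,7.73,false
45,f,29.8,17,0,n/a,1,8.78,false
46,m,53.9,9,0,n/a,2,8.42,false
47,f,27.1,14,0,n/a,2,8.22,false
48,m,66.0,5,0,n/a,3,8.81,false
50,f,13.4,22,0,n/a,2,6.76,false
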