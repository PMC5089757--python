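patient_id,sex,age_years,exclusion_reason,days_symptom_to_mri,mri_signal_code,etco2_mmHg,swi_score,ttp_frames,anesthesia
15,f,71.0,no EHEC,n/a,n/a,n/a,n/a,n/a,false
20,m,67.2,no EHEC,n/a,n/a,n/a,n/a,n/a,false
23,f,26.4,no 4D MRA,3,0,n/a,2,n/a,false
24,m,38.3,no 4D MRA,1,0,n/a,1,n/a,false
25,f,26.2,no SWI/4D MRA,0,n/a,n/a,n/a,n/a,false
26,m,63.0,no SWI/4D MRA,2,0,n/a,n/a,n/a,false
29,f,35.0,no SWI/4D MRA,19,7,n/a,n/a,n/a,false
30,m,37.5,no 4D MRA,1,6,39,3,n/a,true
33,m,75.0,4D MRA artifacts,3,0,n/a,2,n/a,false
35,f,67.1,no 4D MRA,10,0,n/a,1,n/a,false
36,m,31.5,no EHEC,n/a,n/a,n/a,n/a,n/a,false
40,f,80.0,4D MRA artifacts,n/a,7,n/a,2,n/a,false
44,f,11.8,4D MRA artifacts,n/a,0,n/a,1,n/a,false
49,f,14.3,no SWI/4D MRA,n/a,0,n/a,n/a,n/a,false
51,f,23.0,no SWI,n/a,0,n/a,n/a,7.03,false
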