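sample_id,subject_id,tissue,classification,gender,age_years,onset_age_years,duration_years,laterality,localisation,engel,mri_positive,risk_factors,prior_surgery,spike_enrichment_ratio
D01_brain,D01,brain,Ia,M,31,12,19,R,P,2,true,,false,1.0
D02_brain,D02,brain,IIa,F,18,4,14,R,T,1C,false,,false,1.0
D03_brain,D03,brain,IIa,M,58,8,50,R,F,1A,false,,false,1.0
D04_brain,D04,brain,IIa,F,1.6,0,1.6,R,TPO,2A,,,false,1.0
D05_brain,D05,brain,IIa,M,21,2,19,L,F,1A,true,,false,1.0
D06_brain,D06,brain,IIb,F,41,13,28,L,F,1A,true,,false,1.0
D07_brain,D07,brain,IIb,F,38,13,25,L,F,1A,true,,false,1.0
D08_brain,D08,brain,IIb,M,29,5,24,R,PO,2,true,,false,1.0
D09_brain,D09,brain,IIb,F,41,2,39,L,T,1A,true,,false,1.0
D10_brain,D10,brain,IIIa,F,44,17,27,L,T,4,false,,false,1.0
D11_brain,D11,brain,IIIa,F,66,22,44,L,T,1A,true,,false,1.0
D12_brain,D12,brain,IIIa,F,,25,,R,T,1A,true,,false,1.0
D13_brain,D13,brain,IIId,F,19,2,17,R,F,1B,true,,false,1.0
D14_brain,D14,brain,mMCD,M,21,5,16,L,F,2,false,,false,1.0
D15_brain,D15,brain,mMCD,F,57,23,34,R,T,1A,false,,false,1.0
D16_brain,D16,brain,MOGHE,M,8,0,8,L,F,,true,,false,1.0
D17_brain,D17,brain,MOGHE,F,48,20,28,R,F,1A,true,,false,1.0
D18_brain,D18,brain,MOGHE,F,34,6,28,L,F,1A,true,,false,1.0
D19_brain,D19,brain,PMG,F,37,0,37,R,P,3,true,,false,1.0
D20_brain,D20,brain,nonMCD,M,102,49,53,L,T,1A,false,,false,1.0
D21_brain,D21,brain,nonMCD,M,85,36,49,L,T,3,true,,false,1.0
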