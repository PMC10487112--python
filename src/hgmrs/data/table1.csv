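patient,age,sex,idh,histology,grade,location,mrs_elevation_pct,exvivo_hg,exvivo_over_mrs,pv_label
1,60,F,R132H,DA,II,Temporal (L),29,1.73,0.060,TP
2,32,M,R132C,DA,II,Frontal (R),5,3.19,0.638,TP
3,54,F,R132H,DA,II,Frontal (R),28,2.66,0.095,TP
4,48,M,R132H,DA,II,Frontal (R),17,2.17,0.128,TP
5,30,M,R132H,DA,II,Midline,16,1.09,0.068,TP
6,34,M,R132H,DA,II,Temporo-occipital (L),2,0.33,0.165,TP
7,30,F,R132H,DA,IV,Fronto-parietal (R),-3,0.29,-0.097,FN
8,24,M,R132S,DA,II,Frontal (L),192,7.66,0.040,TP
9,56,M,WT,GBM,IV,Fronto-temporal (L),-2,0.05,-0.025,TN
10,25,M,R132H,DA,II,Frontal (L),-7,1.38,-0.197,FN
11,27,F,R132C,DA,II,Frontal (L),19,5.51,0.290,TP
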