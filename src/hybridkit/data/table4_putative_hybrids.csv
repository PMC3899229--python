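id,year,phenotype,mtdna,y_str,k,st0_q39,st0_q24,st0_q12,st1_q39,st1_q24,st1_q12,gc_39,gc_24,gc_12,flock_39,baps_39,nh_39,final_id
1,1997,Dog-like,D15,YH17,+,0.439,0.472,0.405,0.448,0.468,0.382,99.9,100,98.4,HY,HY,F1,F1
2,1999,Spur,W14,YH17,+,0.690,0.700,0.914,0.684,0.706,0.866,100,100,98.7,HY,HY,F2-BC,F2
3,2007,unknown,W14,female,B,0.625,0.459,0.602,0.629,0.470,0.600,100,100,100,HY,HY,F2,F2
4,1999,Spur; dark coat,W14,YH17,B,0.886,0.934,0.960,0.860,0.890,0.862,99.9,99.8,52.7,HY,W,BC,BC
5,2001,White nails,W14,female,+,0.760,0.833,0.957,0.759,0.811,0.853,100,100,99.1,HY,HY,BC,BC
6,2006,White nails,W14,female,+,0.833,0.900,0.959,0.818,0.842,0.884,100,100,95.1,HY,HY,BC,BC
7,2011,Brown coat,W14,YH17,+,0.855,0.809,0.839,0.846,0.798,0.794,100,100,99.9,HY,HY,BC,BC
8,2007,Spur,W14,female,+,0.795,0.774,0.989,0.772,0.754,0.971,100,100,17.9,HY,HY,BC,BC
9,2007,Dark coat,W16,YH26,+,0.995,0.987,0.989,0.984,0.963,0.968,2.5,71.1,94.3,HY,W,W,BC
10,2006,wild-type,W14,YH17,+,0.972,0.946,0.979,0.919,0.886,0.920,99.9,99.9,99.8,HY,W,W,BC
11,2011,wild-type,W14,YH32,+,0.661,0.592,0.686,0.646,0.591,0.629,100,100,100,HY,HY,BC,BC
12,2012,wild-type,W14,female,+,0.882,0.971,0.993,0.871,0.930,0.982,100,97.0,23.1,HY,W,BC,BC
13,2012,unknown,W14,YH05,+,0.837,0.740,0.958,0.826,0.791,0.929,100,100,66.6,HY,HY,BC,BC
14,2009,unknown,W14,YH05,+,0.988,0.979,0.977,0.971,0.956,0.956,95.9,44.9,87.4,W,W,W,BC
15,2011,wild-type,W14,YH17,+,0.940,0.977,0.992,0.906,0.941,0.980,99.9,99.6,7.0,W,W,W-BC,BC
16,2006,unknown,W14,female,+,0.977,0.977,0.958,0.951,0.947,0.901,97.9,68.4,99.5,W,W,W,BC
17,2002,Black coat,W14,YH17,B,0.997,0.996,0.988,0.993,0.989,0.963,6.3,2.4,75.3,W,W,W,IG
18,2009,Black coat,W14,female,B,0.998,0.997,0.993,0.995,0.992,0.980,0.0,0.0,9.2,W,W,W,IG
19,2009,Dog-like; dark,W14,YH17,B,0.996,0.995,0.993,0.989,0.982,0.982,1.3,43.1,36.3,W,W,W,IG
20,2000,Black coat,W14,female,B,0.997,0.996,0.991,0.993,0.988,0.978,6.5,10.0,46.9,W,W,W,IG
21,2012,White nails,W14,YH17,+,0.998,0.997,0.994,0.994,0.991,0.985,0.0,8.2,4.3,W,W,W,IG
22,2011,unknown,W16,female,+,0.998,0.997,0.993,0.994,0.991,0.978,0.0,0.0,54.5,W,W,W,IG
23,2010,unknown,W16,YH26,+,0.995,0.993,0.986,0.979,0.964,0.935,98.6,99.0,99.0,W,W,W,IG
24,2006,unknown,W14,YH17,B,0.995,0.997,0.989,0.986,0.992,0.964,13.4,0.0,30.2,W,W,W,IG
25,2007,wild-type,W14,YH17,+,0.997,0.997,0.990,0.989,0.986,0.962,0.0,6.4,12.5,W,W,W,FP
26,2006,wild-type,W14,female,+,0.995,0.994,0.978,0.980,0.969,0.905,9.6,47.5,99.4,W,W,W,FP
27,2007,wild-type,W14,YH17,+,0.996,0.995,0.990,0.988,0.980,0.958,8.8,25.2,84.4,W,W,W,FP
28,1997,wild-type,W14,female,+,0.997,0.996,0.981,0.980,0.966,0.867,2.6,63.4,95.6,W,W,W,FP
29,2010,wild-type,W14,YH17,+,0.997,0.996,0.992,0.988,0.979,0.962,11.4,46.1,97.3,W,W,W,FP
30,2006,wild-type,W14,YH17,+,0.996,0.993,0.979,0.984,0.979,0.944,4.1,27.2,77.9,W,W,W,FP
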