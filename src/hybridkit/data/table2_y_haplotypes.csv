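haplotype,DIT,DAP,DCZ,WIT,WCZ,WHR,WDCZ,HYIT
YH01,0,0,0,0,0,0,19,0
YH05,6,14,6,0,0,0,10,2
YH06,6,0,0,0,0,0,0,0
YH08,0,0,0,0,0,3,0,0
YH09,0,0,0,0,0,1,0,0
YH11,0,0,0,0,2,3,0,0
YH16,0,0,0,0,1,1,0,0
YH17,0,0,0,27,0,0,0,13
YH20,0,0,0,0,0,6,0,0
YH24,1,0,0,0,0,0,0,0
YH26,0,0,0,4,0,0,0,2
YH27,1,0,0,0,0,0,0,0
YH28,1,0,0,0,0,0,0,0
YH31,0,0,0,0,2,1,0,0
YH32,0,0,0,0,0,0,0,1
YH33,0,0,0,0,0,1,0,0
YH34,3,1,0,0,0,0,0,0
Total males,18,15,6,31,5,16,29,18
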