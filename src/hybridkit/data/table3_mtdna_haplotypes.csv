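haplotype,DIT,DAP,DCZ,WIT,WCZ,WHR,WDCZ,HYIT
D01,6,3,0,0,0,0,0,0
D05,1,2,0,0,0,0,0,0
D06,0,0,1,0,0,0,0,0
D08,3,0,0,0,0,0,0,0
D09,3,5,0,0,0,0,0,0
D10,2,0,0,0,0,0,0,0
D13,0,0,2,0,0,0,47,0
D14,13,3,3,0,0,0,0,0
D15,2,13,0,0,0,0,0,1
D16,1,0,0,0,0,0,0,0
D17,0,0,1,0,0,0,0,0
D18,0,0,4,0,0,0,22,0
H6,0,0,0,0,2,0,0,0
H14,0,0,0,0,6,0,0,0
W1,0,0,0,0,0,13,0,0
W2,0,0,0,0,0,1,0,0
W6,0,0,0,0,0,12,0,0
W14,0,0,0,63,0,0,0,26
W16,0,0,0,0,0,0,0,3
Total samples,31,26,11,63,8,26,69,30
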