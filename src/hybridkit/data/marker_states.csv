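marker,label,state
mtdna,W14,local_wolf
mtdna,W16,nonlocal_wolf
mtdna,W1,nonlocal_wolf
mtdna,W2,nonlocal_wolf
mtdna,W6,nonlocal_wolf
mtdna,H6,nonlocal_wolf
mtdna,H14,nonlocal_wolf
mtdna,D01,dog
mtdna,D05,dog
mtdna,D06,dog
mtdna,D08,dog
mtdna,D09,dog
mtdna,D10,dog
mtdna,D13,dog
mtdna,D14,dog
mtdna,D15,dog
mtdna,D16,dog
mtdna,D17,dog
mtdna,D18,dog
y,YH17,local_wolf
y,YH26,local_wolf
y,YH05,dog_shared
y,YH32,private
y,YH01,dog_shared
y,YH06,dog_shared
y,YH24,dog_shared
y,YH27,dog_shared
y,YH28,dog_shared
y,YH34,dog_shared
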