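region,start,end
Ntt,1,39
TMH1,40,69
ICL1,70,77
TMH2,78,103
ECL1,104,112
TMH3,113,150
ICL2,151,163
TMH4,164,185
ECL2,186,189
TMH5,190,222
ICL3,223,242
TMH6,243,269
ECL3,270,281
TMH7,282,308
H8,309,320
Ctt,321,332
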