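class,count,status
CE,25,confirmed
FFA,27,confirmed
LysoPC,30,confirmed
DG,847,probable
PC,1092,probable
PE,1071,probable
TG,289,probable
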