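panel_name,biocrates_mean,biocrates_sd,lipomics_name,lipomics_mean,lipomics_sd
LysoPC a C14:0,2.64,0.31,,4.23,1.67
LysoPC a C16:0,124.1,50.46,,106.6,16.73
LysoPC a C16:1,3.6,1.12,,2.34,1.05
LysoPC a C17:0,2.36,1.04,,ND,ND
LysoPC a C18:0,40.77,20.55,,47.54,8.38
LysoPC a C18:1,30.94,10.05,LysoPC C18:1n7,3.66,0.14
,,,LysoPC C18:1n9,37.47,7.73
,,,LysoPC dm18:1n9,0.13,NA
LysoPC a C18:2,32.98,13.31,,52.75,6.48
LysoPC a C20:3,2.53,0.74,LysoPC C20:3n6,2.75,0.29
,,,LysoPC C20:3n9,0.25,0.07
LysoPC a C20:4,6.13,2.47,LysoPC C20:4n6,8.39,0.98
,,,LysoPC C20:4n3,0.26,0.14
LysoPC a C24:0,0.19,NA,,0.70,0.35
LysoPC a C28:0,0.37,0.06,,ND,ND
LysoPC a C28:1,0.48,0.1,,ND,ND
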