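parent_lipid,class,hmdb_id,abbreviation,pennington
C16:0,Ethanolamide,HMDB02100,PEA,25.1±12
C18:0,Ethanolamide,HMDB13078,SEA,15±11
C18:1n9,Ethanolamide,HMDB02088,OEA,46.8±34
C18:2n6,Ethanolamide,HMDB12252,LEA,13.7±6.5
C18:3n3,Ethanolamide,HMDB13624,Alpha-LEA,0.118±0.069
C20:3n6,Ethanolamide,HMDB13625,DGLA EA,1.01±0.48
C20:4n6,Ethanolamide,HMDB04080,AEA,3.12±1.2
C22:4n6,Ethanolamide,HMDB13626,DEA,1.63±0.78
C22:6n3,Ethanolamide,HMDB13627,DHEA,0.401±0.22
PGF2a,Ethanolamide,HMDB13628,PGF2a EA,0.0173±0.015
PGD2,Ethanolamide,HMDB13629,PGD2 EA,0.161±0.032
20-HETE,Ethanolamide,HMDB13630,20-HETE EA,0.0208±0.013
C18:1n9,1-Acyl Glycerol,HMDB11567,1-OG,170±170
C18:2n6,1-Acyl Glycerol,HMDB11568,1-LG,37.6±36
C20:4n6,1-Acyl Glycerol,HMDB11578,1-AG,4.71±4.5
C18:1n9,2-Acyl Glycerol,HMDB11537,2-OG,166±130
C18:2n6,2-Acyl Glycerol,HMDB11538,2-LG,146±97
C20:4n6,2-Acyl Glycerol,HMDB04666,2-AG,7.8±4.6
C18:1n9,N-Acyl Glycine,HMDB13631,NO-Gly,21±23
C20:4n6,N-Acyl Glycine,HMDB05096,NA-Gly,1.09±0.73
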