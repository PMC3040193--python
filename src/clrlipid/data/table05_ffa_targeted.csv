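name,class,hmdb_id,abbreviation,mean,sd
Dodecanoic acid,SAT,HMDB00638,C12:0,1.47,0.68
Myristic acid,SAT,HMDB00806,C14:0,7.16,3
Pentadecanoate,SAT,HMDB00826,C15:0,1.34,0.91
Palmitic acid,SAT,HMDB00220,C16:0,122,48
Heptadecanoic acid,SAT,HMDB02259,C17:0,1.89,0.92
Stearic acid,SAT,HMDB00827,C18:0,48.8,21
Palmitelaidic acid,MUFA,HMDB12328,C16:1n7t,1.97,1.4
Palmitoleic acid,MUFA,HMDB03229,C16:1n7,9.66,6.8
Vaccenic acid,MUFA,HMDB03231,C18:1n7,10.7,5
Oleic acid,MUFA,HMDB00207,C18:1n9,122,56
Nonadeca-10(Z)-enoic acid,MUFA,HMDB13622,C19:1n9,0.646,0.37
Eicosenoic acid,MUFA,HMDB02231,C20:1n9,0.663,0.59
Linoleic acid,PUFA,HMDB00673,C18:2n6,83.8,38
Gamma-Linolenic acid,PUFA,HMDB03073,C18:3n6,1.08,1.5
Bovinic acid,PUFA,HMDB03797,"C18:2(9c/t,11t)-CLA",2.03,1.3
Alpha-Linolenic acid,PUFA,HMDB01388,C18:3n3,5.11,3.8
Mead acid,PUFA,HMDB10378,C20:3n9,0.987,0.45
Dihomo-gamma-linolenic acid,PUFA,HMDB02925,C20:3n6,3.61,2.1
Arachidonic acid,PUFA,HMDB01043,C20:4n6,14,12
Adrenic acid,PUFA,HMDB02226,C22:4n6,1.01,0.48
"4,7,10,13,16-Docosapentaenoic acid",PUFA,HMDB13123,C22:5n6,0.953,0.51
Stearidonic acid,PUFA,HMDB06547,C18:4n3,0.408,0.4
Timnodonic acid; EPA,PUFA,HMDB01999,C20:5n3,1.09,0.72
Clupanodonic acid; DPA,PUFA,HMDB06528,C22:5n3,0.993,0.46
Cervonic acid; DHA,PUFA,HMDB02183,C22:6n3,4.66,3.3
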