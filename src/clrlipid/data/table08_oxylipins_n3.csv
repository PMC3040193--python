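parent_lipid,class,hmdb_id,abbreviation,hm_replicate,pennington
C20:5n3,R-OH,HMDB10209,15-HEPE,0.28±0.042,1.63±1.6
C20:5n3,R-OH,HMDB10202,12-HEPE,3.19±0.35,0.195±0.11
C20:5n3,R-OH,HMDB05081,5-HEPE,1.15±0.14,0.228±0.091
C20:5n3,Diol,HMDB10211,"17,18-DiHETE",14.4±1.1,2.08±0.85
C20:5n3,Diol,HMDB10204,"14,15-DiHETE",ND,0.304±0.1
C20:5n3,Epox,HMDB10212,"17,18-EpETE",ND,0.0733±0.095
C20:5n3,Epox,HMDB10205,"14,15-EpETE",0.119±0.029,<0.1
C20:5n3,LT,HMDB05073,LTB5,0.079±0.0056,<0.1
C20:5n3,PG,HMDB02664,PGE3,ND,<0.1
C20:5n3,Triol,HMDB10410,Resolvin E1,1.00±0.23,0.521±0.98
C22:6n3,Epox,HMDB13620,19(20)-EpDoPE,ND,<0.1
C22:6n3,Epox,HMDB13621,16(17)-EpDoPE,ND,0.368±0.43
C22:6n3,Diol,HMDB10214,"19,20-DiHDoPE",ND,0.805±0.42
C22:6n3,R-OH,HMDB10213,17-HDoHE,ND,0.773±0.64
C22:6n3,Triol,HMDB03733,Resolvin D1,ND,0.0454±0.027
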