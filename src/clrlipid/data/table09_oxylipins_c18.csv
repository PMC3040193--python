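parent_lipid,class,hmdb_id,abbreviation,hm_replicate,pennington
C18:2n6,Diol,HMDB04705,"12,13-DiHOME",7.69±0.59,5.82±3
C18:2n6,Diol,HMDB04704,"9,10-DiHOME",60.5±3.8,29.7±11
C18:2n6,Epox,HMDB04702,12(13)-EpOME,4.88±0.34,7.21±8.8
C18:2n6,Epox,HMDB04701,9(10)-EpOME,2.17±0.23,5.47±7.4
C18:2n6,R-OH,HMDB04667,13-HODE,47.3±0.53,58.2±28
C18:2n6,R-OH,HMDB10223,9-HODE,11.7±0.23,11±6.1
C18:2n6,R-OOH,HMDB03871,13-HpODE,ND,6.01±5.5
C18:2n6,R-OOH,HMDB06940,9-HpODE,ND,5.14±3.8
C18:2n6,"Epox,R=O",HMDB13623,12(13)Ep-9-KODE,3.02±0.27,3.96±2.4
C18:2n6,R=O,HMDB04668,13-KODE,4.82±0.68,1.7±1.2
C18:2n6,R=O,HMDB04669,9-KODE,2.41±0.29,5.3±2.7
C18:2n6,Triol,HMDB04708,"9,12,13-TriHOME",0.827±0.21,4.11±2.2
C18:2n6,Triol,HMDB04710,"9,10,13-TriHOME",0.513±0.083,1.16±0.64
C18:3n3,Diol,HMDB10208,"15,16-DiHODE",14.5±1,5.93±2.4
C18:3n3,Diol,HMDB10201,"12,13-DiHODE",<0.2,0.219±0.12
C18:3n3,Diol,HMDB10221,"9,10-DiHODE",2.36±0.15,0.114±0.085
C18:3n3,Epox,HMDB10206,15(16)-EpODE,3.27±0.23,2.77±2.1
C18:3n3,Epox,HMDB10200,12(13)-EpODE,0.416±0.08,0.468±0.67
C18:3n3,Epox,HMDB10220,9(10)-EpODE,2.08±0.075,1.65±2.3
C18:3n3,R-OH,HMDB10203,13-HOTE,1.9±0.21,1.11±0.74
C18:3n3,R-OH,HMDB10224,9-HOTE,1.98±0.12,1.19±0.91
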