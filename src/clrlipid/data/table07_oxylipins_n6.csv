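parent_lipid,class,hmdb_id,abbreviation,hm_replicate,pennington
C20:4n6,R-OH,HMDB05998,20-HETE,1.77±0.43,0.917±0.58
C20:4n6,R-OH,HMDB03876,15-HETE,1.8±0.098,2.04±1.2
C20:4n6,R-OH,HMDB04682,11-HETE,0.425±0.0095,0.401±0.36
C20:4n6,R-OH,HMDB06111,12-HETE,6.42±0.74,3.95±3.3
C20:4n6,R-OH,HMDB10222,9-HETE,0.304±0.072,0.166±0.16
C20:4n6,R-OH,HMDB04679,8-HETE,2.09±0.16,0.536±0.4
C20:4n6,R-OH,HMDB11134,5-HETE,0.901±0.029,1.02±0.79
C20:4n6,R=O,HMDB10210,15-KETE,0.749±0.08,0.682±0.76
C20:4n6,R=O,HMDB13633,12-KETE,<0.1,<0.1
C20:4n6,R=O,HMDB10217,5-KETE,0.136±0.018,0.145±0.12
C20:4n6,R-OOH,HMDB04244,15-HPETE,NA,1.06±0.41
C20:4n6,R-OOH,HMDB04243,12-HPETE,NA,1.45±2.3
C20:4n6,Diol,HMDB04385,Lipoxin A4,<0.07,<0.07
C20:4n6,Diol,HMDB01085,LTB4,0.0968±0.0062,<0.1
C20:4n6,Diol,HMDB05087,6-trans-LTB4,0.223±0.042,<0.1
C20:4n6,Triol,HMDB01509,20-hydroxy-LTB4,NA,<0.1
C20:4n6,Diol,HMDB06059,20-carboxy-LTB4,NA,<1
C20:4n6,Diol,HMDB10216,"5,15-DiHETE",0.247±0.02,<0.07
C20:4n6,Diol,HMDB10219,"8,15-DiHETE",<0.1,<0.1
C20:4n6,Diol,HMDB02265,"14,15-DiHETrE",0.714±0.031,0.603±0.18
C20:4n6,Diol,HMDB02314,"11,12-DiHETrE",0.779±0.037,0.566±0.2
C20:4n6,Diol,HMDB02311,"8,9-DiHETrE",0.294±0.056,0.244±0.078
C20:4n6,Diol,HMDB02343,"5,6-DiHETrE",0.264±0.025,0.189±0.092
C20:4n6,Epox,HMDB04693,14(15)-EpETrE,1.77±0.05,0.442±0.59
C20:4n6,Epox,HMDB10409,11(12)-EpETrE,0.303±0.028,1.02±1.4
C20:4n6,Epox,HMDB02232,8(9)-EpETrE,<0.2,0.627±0.71
C20:4n6,Epox,HMDB04688,Hepoxilin A3,NA,0.114±0.087
C20:4n6,LT,HMDB02200,LTE4,NA,<0.6
C20:4n6,TX,HMDB03252,TXB2,0.865±0.18,0.919±1.6
C20:4n6,PG,HMDB02886,6-keto-PGF1a,0.359±0.023,0.0607±0.028
C20:4n6,PG,HMDB01139,PGF2a,0.33±0.018,0.248±0.13
C20:4n6,PG,HMDB01220,PGE2,0.0967±0.012,0.172±0.13
C20:4n6,PG,HMDB01403,PGD2,0.0726±0.0058,<0.1
C20:4n6,PG,HMDB02710,PGJ2,<0.3,<0.3
C20:4n6,PG,HMDB04236,PGB2,0.519±0.096,<0.7
C20:4n6,PG,HMDB04238,Delta-12-PGJ2,<0.3,<0.3
C20:4n6,PG,HMDB05079,15-deoxy PGJ2,0.206±0.011,<0.3
C20:4n6,Triol,HMDB04684,"11,12,15-TriHETrE",<0.1,<0.1
C20:3n6,R-OH,HMDB05045,15-HETrE,0.437±0.028,0.732±0.45
C20:3n6,PG,HMDB01442,PGE1,<0.1,<0.1
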