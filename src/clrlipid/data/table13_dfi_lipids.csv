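group,name,mean,sd
sphingomyelin,SM (OH) C14:1,5.92,1.63
sphingomyelin,SM (OH) C16:1,3.70,0.90
sphingomyelin,SM (OH) C22:1,15.6,3.7
sphingomyelin,SM (OH) C22:2,12.89,2.88
sphingomyelin,SM (OH) C24:1,2.56,0.66
sphingomyelin,SM C16:0,100.5,18.6
sphingomyelin,SM C16:1,15.1,3.5
sphingomyelin,SM C18:0,25.8,6.4
sphingomyelin,SM C18:1,11.7,3.0
sphingomyelin,SM C20:2,1.34,0.35
sphingomyelin,SM C22:3,16.4,7.9
sphingomyelin,SM C24:0,30.5,7.6
sphingomyelin,SM C24:1,82.7,14.1
sphingomyelin,SM C26:0,0.440,0.111
sphingomyelin,SM C26:1,0.850,0.167
lysophosphatidylcholine,LysoPC a C14:0,2.64,0.31
lysophosphatidylcholine,LysoPC a C16:0,141,50
lysophosphatidylcholine,LysoPC a C16:1,3.48,1.01
lysophosphatidylcholine,LysoPC a C17:0,2.55,1.08
lysophosphatidylcholine,LysoPC a C18:0,48.5,20.2
lysophosphatidylcholine,LysoPC a C18:1,31.5,10.4
lysophosphatidylcholine,LysoPC a C18:2,30.33,10.3
lysophosphatidylcholine,LysoPC a C20:3,2.65,0.68
lysophosphatidylcholine,LysoPC a C20:4,6.13,2.55
lysophosphatidylcholine,LysoPC a C24:0,0.19,NA
lysophosphatidylcholine,LysoPC a C28:0,0.370,0.043
lysophosphatidylcholine,LysoPC a C28:1,0.481,0.117
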