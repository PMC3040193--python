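chain,ce_mean,ce_sd,ffa_mean,ffa_sd,lysopc_mean,lysopc_sd
C14:0,97.04,59.91,15.46,4.02,4.23,1.67
C15:0,ND,ND,2.69,0.51,1.76,0.85
C16:0,405.46,56.51,66.01,9.88,106.60,16.73
C18:0,37.50,2.82,41.12,5.52,47.54,8.38
C20:0,1.18,0.12,0.87,0.09,0.69,0.37
C22:0,1.08,0.48,1.01,0.26,0.43,0.09
C24:0,0.91,0.55,0.93,0.19,0.70,0.35
C14:1n5,4.19,1.04,2.02,0.73,0.21,0.08
C16:1n7,118.75,45.54,6.39,4.28,2.34,1.05
C18:1n7,44.23,3.82,2.55,1.31,3.66,0.14
C18:1n9,704.47,129.59,49.24,19.31,37.47,7.73
C20:1n9,0.11,NA,1.50,1.21,0.53,0.17
C20:3n9,2.80,1.49,1.32,1.36,0.25,0.07
C22:1n9,1.86,2.43,1.26,1.59,0.57,0.26
C24:1n9,ND,ND,0.90,0.97,0.73,0.56
C18:2n6,1506.38,204.89,14.73,4.33,52.75,6.48
C18:3n6,23.66,1.58,0.31,0.20,0.23,0.10
C20:2n6,4.29,4.02,0.42,0.16,0.71,0.25
C20:3n6,18.71,5.94,0.42,0.21,2.75,0.29
C20:4n6,195.48,21.36,5.26,2.07,8.39,0.98
C22:2n6,1.06,NA,0.42,0.07,0.10,0.11
C22:4n6,ND,ND,ND,ND,0.13,NA
C22:5n6,3.28,3.46,0.14,0.09,0.11,0.02
C18:3n3,23.60,0.13,1.98,1.22,1.24,0.54
C18:4n3,ND,ND,ND,ND,0.29,0.32
C20:4n3,2.47,1.96,0.01,NA,0.26,0.14
C20:5n3,39.07,11.07,0.40,0.07,1.61,0.16
C22:5n3,3.22,3.67,0.39,0.23,0.74,0.22
C22:6n3,21.93,6.64,1.78,0.80,2.78,0.29
dm16:0,ND,ND,ND,ND,0.93,0.11
dm18:0,ND,ND,ND,ND,0.07,NA
dm18:1n9,ND,ND,ND,ND,0.13,NA
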