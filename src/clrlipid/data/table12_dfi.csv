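group,name,mean,sd
acylcarnitine,DL-carnitine,29.738,7.547
acylcarnitine,Decanoylcarnitine,0.260,0.111
acylcarnitine,Decenoylcarnitine,0.171,0.041
acylcarnitine,Decadienylcarnitine,0.061,0.029
acylcarnitine,Dodecanoylcarnitine,0.103,0.030
acylcarnitine,Tetradecanoylcarnitine,0.043,0.007
acylcarnitine,Tetradecenoylcarnitine,0.063,0.028
acylcarnitine,Tetradecadienylcarnitine,0.028,0.013
acylcarnitine,Hexadecanoylcarnitine,0.072,0.019
acylcarnitine,Hexadecenoylcarnitine,0.029,0.005
acylcarnitine,Hexadecadienylcarnitine,0.012,0.002
acylcarnitine,Octadecanoylcarnitine,0.035,0.010
acylcarnitine,Octadecenoylcarnitine,0.108,0.036
acylcarnitine,Octadecadienylcarnitine,0.035,0.013
acylcarnitine,Acetyl-L-carnitine,5.476,2.147
acylcarnitine,Propionyl-L-carnitine,0.313,0.154
acylcarnitine,Butyryl-L-carnitine,0.262,0.158
acylcarnitine,Hydroxybutyrylcarnitine,0.106,0.010
acylcarnitine,Valeryl-L-carnitine,0.142,0.063
acylcarnitine,Tiglyl-L-carnitine,0.045,0.005
acylcarnitine,Glutaconyl-L-carnitine,0.018,0.002
acylcarnitine,Octanoylcarnitine,0.234,0.078
acylcarnitine,Octenoylcarnitine,0.200,0.151
acylcarnitine,Nonaylcarnitine,0.033,0.013
amino_acid,L-Arginine,129.5,30.0
amino_acid,L-Glutamine,492.6,93.6
amino_acid,Glycine,329.9,105.6
amino_acid,L-Histidine,143.1,27.3
amino_acid,L-Isoleucine+L-Leucine,227.4,63.5
amino_acid,L-Methionine,33.4,9.0
amino_acid,L-Ornithine,93.8,41.3
amino_acid,L-Pheylalanine,85.2,23.0
amino_acid,L-Proline,177.5,38.6
amino_acid,L-Serine,173.2,51.3
amino_acid,L-Threonine,102.3,24.6
amino_acid,L-Tryptophan,78.4,15.5
amino_acid,L-Tyrosine,143.0,35.3
amino_acid,L-Valine,266.3,61.0
hexose,Hexose,3767.6,607.0
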