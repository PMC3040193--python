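name,mean_uM,literature_value
Oxalic acid,22.2,9.2±2.7
Acetylglycine,69.7,109.4±85.6
Myo-inositol,17.1,23.0±8.0
Uric acid,494.2,302±60
Succinic acid,23.5,16.0 (0.0–32.0)
Alpha-Hydroxyisobutyric acid,8.2,7.0 (0.0–9.0)
Ribitol/D-Xylitol,<5,0.46 (0.38–0.55)
Erythronic acid,<5,2.5 (0.0–5.0)
Lauric (Dodecanoic) acid,9.1,12.0 (2.0–37.0)
Phosphoric acid,820.4,1100 (810–1450)
Myristic (Tetradecanoic) acid,9.3,15.4±4.0
Gluconic acid,<5,NA
D-Maltose/L-Arabinose,<5,2.5 (0.0–5.0)
Glyceric acid,<5,2.5 (0.0–5.0)
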