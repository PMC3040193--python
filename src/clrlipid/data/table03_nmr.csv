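name,healthy_mean,healthy_sd,healthy_occurrence_pct,transplant_mean,transplant_sd,transplant_occurrence_pct,literature_value
2-Hydroxybutyric acid,31.3,7.8,73,24.3,14.5,92,54; (8–80)
Alpha-ketoisovaleric acid,ND,,,10.7,5.5,40,NA
3-Hydroxybutyric acid,76.9,66.3,80,35.1,33.9,96,60.0±20.0
Acetaminophen,ND,,,33.5,22.3,8,NA
Acetic acid,41.9,15.1,100,42.2,17.3,100,30; (22–40)
Acetoacetic acid,40.6,36.5,33,27.3,14.4,25,21.0; (0.0–86.0)
Acetone,54.4,29.6,86,13.2,5.5,4,106; (35–170)
L-Alanine,427.2,84.4,100,340,126.2,100,333; (259–407)
L-Arginine,113.6,14.6,100,ND,,,111.6; (82.2–140.9)
L-Asparagine,82.4,7.3,100,54.1,21.7,42,41±10
L-Aspartic acid,20.9,6.1,100,ND,,,21.0+/−5.0
Betaine,72,22.4,100,42.1,19.3,100,82; (20–144)
L-Carnitine,45.7,11.6,100,41.7,23.9,100,43; (26–79)
Choline,14.5,5.3,90,9.7,4.5,92,10.6±1.9
Citric acid,114.2,27,100,80.2,44.9,100,190; (30–400)
Creatine,36.7,28.3,100,33.8,37.7,100,54.8±21.0
Creatinine,86.6,18.8,100,86.9,44.5,100,74.1±10.9
L-Cysteine,33.5,10.3,100,ND,,,52.0; (41.0–63.0)
L-Cystine,62.9,27.8,100,ND,,,109.0±24.0
Ethanol,ND,,,40.2,12.1,13,NA
Formic acid,32.8,13.3,48,19.8,6.8,60,121.7±97.8
D-Glucose,4971.3,372.8,100,3743,1272.9,100,5400; (4700–6100)
L-Glutamic acid,97.4,13.2,100,72,36.9,40,21.0–150.0
L-Glutamine,510.4,118.2,100,376.8,114.3,100,586; (502–670)
Glycerol,431.6,100.4,100,133.9,87.8,100,82; (27–137)
Glycine,325.4,126.8,100,234.9,181.1,100,230; (178–282)
L-Histidine,131.2,37.3,100,46.1,17.5,100,82; (72–92)
Hypoxanthine,34.2,10.3,24,52.3,NA,2,8.1; (5.3–11.0)
Isobutyric acid,ND,,,8.4,1.9,11,NA
L-Isoleucine,60.7,18.6,100,44.6,21.5,100,62; (48–76)
Isopropyl alcohol,83.3,132.8,48,16.5,22.5,45,Not available
L-Lactic acid,1489.4,371.2,100,1401.2,692.1,100,1510; (740–2400)
L-Leucine,98.7,11.5,100,74.8,34.3,100,123; (98–148)
L-Lysine,178.6,58.2,100,128.2,55.3,100,183.0±34.0
Malonic acid,13.5,1.2,14,105.7,95.8,9,15.0±0.6
Methanol,77.4,16.3,100,81.5,55.2,94,47.2±10.3
L-Methionine,29.8,6.3,33,17.3,9.5,66,30; (22–38)
Methylmalonic acid,ND,,,11.2,NA,2,NA
L-Ornithine,66.9,15.3,100,65.4,30.4,100,55; (39–71)
L-Phenylalanine,78.1,20.5,100,44.8,21,94,65.0±9.0
L-Proline,198.3,64.8,100,159.9,86.3,100,239.0±70.0
Propylene glycol,22.3,3.3,100,36.3,19.9,62,2; (0–5)
Pyruvic acid,34.5,25.2,81,50.2,40,87,64; (22–258)
L-Serine,159.8,26.6,100,ND,,,137.0±35.0
L-Threonine,127.7,41,100,83.4,47.8,96,140; (107–173)
L-Tryptophan,54.5,9.7,100,ND,,,48.7±11.6
L-Tyrosine,54.5,9.7,100,57.2,24.4,100,100; (55–147)
Urea,6074.6,2154.2,100,3309.9,1844,100,6500; (4000–9000)
L-Valine,212.3,61.3,100,144.2,61.4,100,233; (190–276)
Xanthine,ND,,,51.2,NA,2,NA
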