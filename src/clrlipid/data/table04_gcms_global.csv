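name,category
Glycine,amino_acid
L-Alanine,amino_acid
L-Asparagine,amino_acid
L-Aspartic acid,amino_acid
L-Cysteine,amino_acid
L-Cystine,amino_acid
L-Glutamic acid,amino_acid
L-Glutamine,amino_acid
L-Histidine,amino_acid
L-Isoleucine,amino_acid
L-Leucine,amino_acid
L-Lysine,amino_acid
L-Methionine,amino_acid
L-Ornithine,amino_acid
L-Phenylalanine,amino_acid
L-Proline,amino_acid
L-Serine,amino_acid
L-Threonine,amino_acid
L-Tryptophan,amino_acid
L-Tyrosine,amino_acid
L-Valine,amino_acid
2-aminobutyric acid,organic_acid
Alpha-Hydroxyisobutyric acid,organic_acid
2-Methylbutanoic acid,organic_acid
3-Hydroxybutyric acid,organic_acid
4-Hydroxybutyric acid,organic_acid
Aminomalonic acid,organic_acid
Benzoic acid,organic_acid
Citric acid,organic_acid
Erythronic acid,organic_acid
Fumaric acid,organic_acid
Gluconic acid,organic_acid
Glyceric acid,organic_acid
Isobutyric acid,organic_acid
Tartaric acid,organic_acid
L-Lactic acid,organic_acid
Malonic acid,organic_acid
Methylmaleic acid,organic_acid
Methylmalonic acid,organic_acid
Nicotinic acid,organic_acid
Oxalic acid,organic_acid
Pyroglutamic acid,organic_acid
Succinic acid,organic_acid
Uric acid,organic_acid
Arachidonic acid,lipid
Cholesterol,lipid
Capric acid,lipid
Dodecanoic acid,lipid
Arachidic acid,lipid
Heptadecanoic acid,lipid
Linoleic acid,lipid
Oleic acid,lipid
Palmitelaidic acid,lipid
Palmitic acid,lipid
Stearic acid,lipid
Myristic acid,lipid
D-Fructose,misc
D-Galactopyranose,misc
D-Galactose,misc
Glucitol,misc
D-Glucose,misc
Glycerol,misc
D-Glucopyranose,misc
Hydroxyproline,misc
D-Maltose,misc
Myo-inositol,misc
Acetylglycine,misc
N-Acetyl-L-Lysine,misc
Acetaminophen,misc
Phosphoric acid,misc
Ribitol,misc
Salicylic acid,misc
Urea,misc
D-Xylitol,misc
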