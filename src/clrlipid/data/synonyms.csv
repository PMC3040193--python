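name,canonical
hexose,d-glucose
l-pheylalanine,l-phenylalanine
dl-carnitine,l-carnitine
n-acetyl-glycine,acetylglycine
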