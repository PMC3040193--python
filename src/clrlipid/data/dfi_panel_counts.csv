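category,count
acylcarnitines_quantified,24
amino_acids,14
hexose,1
phosphatidylcholines,73
sphingomyelins,15
lysophosphatidylcholines,12
acylcarnitines_measured,41
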