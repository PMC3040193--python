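platform,identified,quantified
NMR,49,49
GCMS,90,33
LCMSMS_mediator,96,96
TLC_GCFID,3381,3381
DFI_MSMS,139,139
combined,3564,
literature,665,
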