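subsystem	n_down	n_up
Glycan Metabolism	31	312
Lipid Metabolism	100	253
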