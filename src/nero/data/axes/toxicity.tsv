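harmful	beneficial
toxic	nontoxic
noxious	benign
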