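rr_bleed_dab: 1.07
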