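rr_bleed_dab: 0.81
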