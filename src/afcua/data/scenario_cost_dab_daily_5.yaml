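cost_dab_daily: 5.0
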