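label,fraction
adult age 20-49,0.368
female age 20-49,0.18
female age 25-29,0.032
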