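severity,proportion,age_reset
high,0.163,yes
med,0.409,no
low,0.428,no
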