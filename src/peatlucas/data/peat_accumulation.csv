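species,rate_t_c_per_ha_yr
AWC,0.36
CG,0.14
MG,0.12
PP,0.17
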