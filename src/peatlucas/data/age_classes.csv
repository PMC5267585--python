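species,young_min,young_max,intermediate_min,intermediate_max,mature_min,mature_max
AWC,0,8,8,70,70,500
CG,0,15,15,200,200,1000
MG,0,15,15,79,80,200
PP,0,5,5,40,40,400
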