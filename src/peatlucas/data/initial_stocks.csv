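stock,AWC,CG,MG,PP
npp,11.35,10.78,9.29,10.47
live_leaf,5.42,3.00,2.91,3.77
live_wood,103.87,169.52,94.62,122.67
live_root,5.46,4.46,3.68,4.53
leaf_litter,5.03,4.46,4.15,4.55
deadwood,25.07,22.70,13.38,20.38
dead_root,2.54,2.07,1.71,2.11
upper_peat,358.40,358.40,358.40,358.40
deep_peat,537.60,537.60,537.60,537.60
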