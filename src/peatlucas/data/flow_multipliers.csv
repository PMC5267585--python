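from_pool,to_pool,flow_type,AWC,CG,MG,PP
atmosphere,live_leaf,growth,0.268,0.278,0.314,0.285
atmosphere,live_wood,growth,0.194,0.258,0.242,0.230
atmosphere,live_root,growth,0.538,0.464,0.444,0.485
live_leaf,leaf_litter,litterfall,0.340,0.470,0.500,0.420
live_wood,deadwood,mortality,0.021,0.016,0.023,0.018
live_root,dead_root,litterfall,0.528,0.528,0.528,0.528
leaf_litter,upper_peat,humification,0.230,0.250,0.230,0.240
deadwood,upper_peat,humification,0.035,0.050,0.025,0.040
dead_root,upper_peat,humification,0.627,0.585,0.595,0.605
leaf_litter,atmosphere,emission,0.180,0.176,0.229,0.185
deadwood,atmosphere,emission,0.050,0.060,0.085,0.067
dead_root,atmosphere,emission,0.213,0.294,0.275,0.258
upper_peat,atmosphere,emission,0.022,0.019,0.015,0.019
upper_peat,deep_peat,peat_accumulation,0.0012,0.0015,0.0010,0.0010
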