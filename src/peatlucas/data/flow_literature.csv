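from_pool,to_pool,flow_type,AWC,AWC_delta,CG,CG_delta,MG,MG_delta,PP,PP_delta
atmosphere,live_leaf,growth,3.040,0.002,2.995,0.002,2.915,0.002,2.983,0.001
atmosphere,live_wood,growth,2.250,-0.048,2.785,-0.004,2.250,-0.002,2.413,-0.005
atmosphere,live_root,growth,6.105,0.001,4.995,0.007,4.120,0.005,5.073,0.005
live_leaf,leaf_litter,litterfall,2.535,-0.692,2.640,-1.230,2.680,-1.225,2.618,-1.035
live_wood,deadwood,mortality,3.090,-0.909,2.600,0.112,1.420,0.756,2.370,-0.162
live_root,dead_root,litterfall,6.105,-3.222,4.995,-2.640,4.120,-2.177,5.073,-2.681
leaf_litter,upper_peat,humification,1.625,-0.468,1.685,-0.570,1.445,-0.491,1.585,-0.493
deadwood,upper_peat,humification,1.280,-0.403,1.150,-0.015,0.280,0.055,0.903,-0.088
dead_root,upper_peat,humification,5.420,-3.827,4.135,-2.924,3.470,-2.453,4.342,-3.065
leaf_litter,atmosphere,emission,0.091,0.814,0.955,-0.170,1.235,-0.285,1.033,-0.191
deadwood,atmosphere,emission,1.810,-0.557,1.450,-0.088,1.140,-0.003,1.467,-0.102
dead_root,atmosphere,emission,0.685,-0.144,0.860,-0.251,0.650,-0.180,0.732,-0.188
upper_peat,atmosphere,emission,7.940,-0.290,7.510,-0.810,6.260,-0.526,7.240,-0.392
upper_peat,deep_peat,peat_accumulation,0.360,0.007,0.120,0.009,0.140,0.011,0.170,0.010
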