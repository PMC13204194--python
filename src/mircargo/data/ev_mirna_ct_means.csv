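target_id,ev_ct_mean,ev_ct_se,medium_ct_mean,medium_ct_se,is_spike_in
ath-miR159a,23.852,1.088,19.240,0.073,True
let-7e-5p,23.738,0.173,Undetermined,Undetermined,False
let-7g-5p,25.016,0.390,Undetermined,Undetermined,False
miR-140-5p,24.379,0.387,Undetermined,Undetermined,False
miR-152-3p,24.662,0.177,Undetermined,Undetermined,False
miR-185-5p,27.472,0.189,Undetermined,Undetermined,False
miR-195-5p,27.445,0.390,Undetermined,Undetermined,False
miR-26a-5p,22.512,0.396,Undetermined,Undetermined,False
miR-29b-3p,23.311,0.768,Undetermined,Undetermined,False
miR-30b-5p,23.602,0.373,Undetermined,Undetermined,False
miR-30c-5p,23.910,0.427,Undetermined,Undetermined,False
miR-324-5p,26.354,0.391,Undetermined,Undetermined,False
miR-34a-5p,22.985,0.913,Undetermined,Undetermined,False
miR-365a/b-3p,24.384,0.463,Undetermined,Undetermined,False
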