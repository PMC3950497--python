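animal_id,dose_mg,cmax_ng_ml,tmax_min,k1_per_min,kel_per_min,c0_ng_ml
ST01,0.50,13.9,90,0.01,0.005,10.57
ST02,0.50,33.9,90,0.025,0.006,21.4
ST03,0.45,20.4,90,0.02,n/a,n/a
ST04,0.45,14.2,90,0.013,0.007,22.5
ST05,0.50,21.2,90,0.02,0.006,15.3
ST06,0.50,25.8,90,0.023,0.007,17.1
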