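animal_id,time_min,conc_ng_ml,conc_sd_ng_ml,dose_mg
ST01,0,0,0,0.50
ST01,15,8.1,0.6,0.50
ST01,30,9.4,0.5,0.50
ST01,60,10.0,0.3,0.50
ST01,90,13.9,0.9,0.50
ST01,120,5.8,0.1,0.50
ST01,180,3.8,0.1,0.50
ST01,480,1.8,0.02,0.50
ST01,720,1.5,0.02,0.50
ST01,1440,0,0,0.50
ST02,0,0,0,0.50
ST02,15,7.9,0.2,0.50
ST02,30,16.5,0.8,0.50
ST02,60,29.3,2.2,0.50
ST02,90,33.9,2.8,0.50
ST02,120,10.4,0.5,0.50
ST02,180,7.8,0.3,0.50
ST02,480,1.2,0.02,0.50
ST02,720,1.3,0.01,0.50
ST02,1440,0,0,0.50
ST03,0,0,0,0.45
ST03,15,6.8,0.4,0.45
ST03,30,14.8,0.2,0.45
ST03,60,19.5,0.6,0.45
ST03,90,20.4,1.7,0.45
ST03,120,6.5,0.1,0.45
ST03,180,n/a,n/a,0.45
ST03,480,n/a,n/a,0.45
ST03,720,n/a,n/a,0.45
ST03,1440,n/a,n/a,0.45
ST04,0,0,0,0.45
ST04,15,5.7,0.2,0.45
ST04,30,7.3,0.3,0.45
ST04,60,9.5,0.5,0.45
ST04,90,14.2,0.2,0.45
ST04,120,9.7,0.2,0.45
ST04,180,2.8,0.2,0.45
ST04,480,0.7,0.01,0.45
ST04,720,0.6,0.01,0.45
ST04,1440,0,0,0.45
ST05,0,0,0,0.50
ST05,15,6.3,0.2,0.50
ST05,30,12.7,0.3,0.50
ST05,60,18.5,0.2,0.50
ST05,90,21.2,0.2,0.50
ST05,120,5.1,0.3,0.50
ST05,180,2.9,0.07,0.50
ST05,480,1.4,0.08,0.50
ST05,720,0.9,0.04,0.50
ST05,1440,0,0,0.50
ST06,0,0,0,0.50
ST06,15,7.0,0.3,0.50
ST06,30,13.9,0.2,0.50
ST06,60,20.4,0.2,0.50
ST06,90,25.8,0.1,0.50
ST06,120,7.6,0.09,0.50
ST06,180,3.3,0.08,0.50
ST06,480,1.2,0.08,0.50
ST06,720,0.7,0.02,0.50
ST06,1440,0,0,0.50
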