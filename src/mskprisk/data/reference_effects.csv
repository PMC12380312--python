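parameter,range_low,range_high,max_or,ci_low,ci_high,per_sd_coef,sample_sd
sleep_factor_3,0.0,3.2,1.182,1.086,1.302,,
sleep_factor_5,0.0,4.0,1.163,1.131,1.199,0.039,1.04
mobile_dependency,0,74,1.117,1.077,1.161,,
sleep_factor_2,0.0,3.0,1.107,1.044,1.167,,
home_laundry,0,1,1.044,1.02,1.065,,
activity_weightlifting,1,5,1.041,0.99,1.09,,
home_room,0,1,1.040,1.02,1.068,,
genre,0,1,1.032,1.018,1.048,,
home_cleaning,0,1,1.031,1.01,1.052,,
age_group_16_18,0.0,1.0,1.026,1.01,1.047,,
home_area,0,1,1.022,1.004,1.036,,
home_pets,0,1,1.020,1.0,1.037,,
activity_football,1,5,0.943,0.927,0.962,,
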