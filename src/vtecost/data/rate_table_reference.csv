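drug,monitoring_usd,initial_rate_pct,final_rate_printed,final_rate_dp,arr_printed,arr_dp,nnt,final_rate_excluded
Aspirin 81,0.00,0.46,0.457,3,0.003,3,31357,0
Aspirin 81,0.00,1.01,1.017,3,0.003,3,31357,1
Aspirin 81,0.00,9.80,9.80,2,0.003,3,31357,0
Aspirin 325,0.00,0.46,0.44,2,0.02,2,5807,0
Aspirin 325,0.00,1.01,1.00,2,0.02,2,5807,1
Aspirin 325,0.00,9.80,9.78,2,0.02,2,5807,0
Enoxaparin 40,0.00,0.46,-1.02,2,1.48,2,68,0
Enoxaparin 40,0.00,1.01,-0.46,2,1.48,2,68,1
Enoxaparin 40,0.00,9.80,8.32,2,1.48,2,68,0
Rivaroxaban 20,0.00,0.46,-4.90,2,5.36,2,19,0
Rivaroxaban 20,0.00,1.01,-4.34,2,5.36,2,19,1
Rivaroxaban 20,0.00,9.80,4.44,2,5.36,2,19,0
Warfarin 5,0.00,0.46,0.44,2,0.02,2,4480,0
Warfarin 5,0.00,1.01,1.00,2,0.02,2,4480,1
Warfarin 5,0.00,9.80,9.78,2,0.02,2,4480,0
Warfarin 5 + INR,6.19,0.46,0.37,2,0.09,2,1135,0
Warfarin 5 + INR,6.19,1.01,0.92,2,0.09,2,1135,0
Warfarin 5 + INR,6.19,9.80,9.71,2,0.09,2,1135,0
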