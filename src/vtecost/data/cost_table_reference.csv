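drug,initial_rate_pct,treatment_cost_usd,final_rate_pct,arr_pct,nnt
Enoxaparin 40,0.46,9407.00,-1.015,1.48,68
Enoxaparin 40,0.46,30000.00,-0.003,0.46,216
Enoxaparin 40,0.46,50000.00,0.182,0.28,360
Enoxaparin 40,0.46,70000.00,0.262,0.20,504
Enoxaparin 40,0.46,90000.00,0.306,0.15,649
Enoxaparin 40,0.46,110000.00,0.334,0.13,793
Rivaroxaban 20,0.46,9407.00,-4.900,5.36,19
Rivaroxaban 20,0.46,30000.00,-1.221,1.68,59
Rivaroxaban 20,0.46,50000.00,-0.548,1.01,99
Rivaroxaban 20,0.46,70000.00,-0.260,0.72,139
Rivaroxaban 20,0.46,90000.00,-0.100,0.56,178
Rivaroxaban 20,0.46,110000.00,0.002,0.46,218
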