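name,dose,route,course_cost_usd,monitoring_cost_usd
Aspirin,81,By mouth,0.30,0.00
Aspirin,325,By mouth,1.62,0.00
Enoxaparin,40,Subcutaneous,138.77,0.00
Rivaroxaban,20,By mouth,504.23,0.00
Warfarin,5,By mouth,2.10,0.00
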