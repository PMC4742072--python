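tag,qbar_ml_hr
baseline,1.146273
nv1_favorable,3.291487
nv1_high_external_pressure,0.008824
nv2_adverse16_pe3,0.389941
nv2_fast_contraction,1.179624
nv2_synchronous,1.020702
nv4_halfcycle_delay_dP6,0.371795
nv4_junction_delay_only,1.533356
nv4_long_diastole_dP0,1.282541
nv4_no_diastole,0.739275
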