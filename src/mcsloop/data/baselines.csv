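condition,impella_level,ecmo_rpm,quantity,value,unit,source,anomaly
normal,P0,0,p_ao_sys,111,mmHg,results_baseline,0
normal,P0,0,p_ao_dia,67,mmHg,results_baseline,0
normal,P0,0,p_ao_mean,88,mmHg,results_baseline,0
normal,P0,0,q_aorta,4.3,L/min,results_baseline,0
normal,P0,0,q_brachio,0.6,L/min,results_baseline,0
normal,P0,0,p_vr_mean,8.1,mmHg,results_baseline,0
normal,P0,0,peak_lvp,137,mmHg,results_baseline,0
normal,P0,0,edp,13,mmHg,results_baseline,0
normal,P0,0,esv,107,ml,results_baseline,0
normal,P0,0,edv,169,ml,results_baseline,0
normal,P0,0,sv,62,ml,results_baseline,0
cs,P0,0,p_ao_sys,75,mmHg,results_baseline,0
cs,P0,0,p_ao_dia,35,mmHg,results_baseline,0
cs,P0,0,p_ao_mean,54,mmHg,results_baseline,0
cs,P0,0,q_aorta,2.8,L/min,results_baseline,0
cs,P0,0,q_brachio,0.4,L/min,results_baseline,0
cs,P0,0,p_vr_mean,13.1,mmHg,results_baseline,0
cs,P0,0,peak_lvp,88,mmHg,results_baseline,0
cs,P0,0,edp,24,mmHg,results_baseline,0
cs,P0,0,esv,148,ml,results_baseline,0
cs,P0,0,edv,199,ml,results_baseline,0
cs,P0,0,sv,51,ml,results_baseline,0
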