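condition,impella_level,ecmo_rpm,quantity,value,unit,source,anomaly
cs,P0,0,total_flow,2.7,L/min,table2,0
cs,P0,1000,total_flow,2.99,L/min,table2,0
cs,P0,1500,total_flow,3.55,L/min,table2,0
cs,P0,2000,total_flow,3.99,L/min,table2,0
cs,P0,2500,total_flow,4.26,L/min,table2,0
cs,P0,3000,total_flow,4.47,L/min,table2,0
cs,P0,0,p_ao_sys,73,mmHg,table2,0
cs,P0,1000,p_ao_sys,73,mmHg,table2,0
cs,P0,1500,p_ao_sys,80,mmHg,table2,0
cs,P0,2000,p_ao_sys,88,mmHg,table2,0
cs,P0,2500,p_ao_sys,97,mmHg,table2,0
cs,P0,3000,p_ao_sys,106,mmHg,table2,0
cs,P0,0,p_ao_dia,23,mmHg,table2,0
cs,P0,1000,p_ao_dia,31,mmHg,table2,0
cs,P0,1500,p_ao_dia,46,mmHg,table2,0
cs,P0,2000,p_ao_dia,61,mmHg,table2,0
cs,P0,2500,p_ao_dia,76,mmHg,table2,0
cs,P0,3000,p_ao_dia,91,mmHg,table2,0
cs,P0,0,p_ao_mean,46,mmHg,table2,0
cs,P0,1000,p_ao_mean,51,mmHg,table2,0
cs,P0,1500,p_ao_mean,62,mmHg,table2,0
cs,P0,2000,p_ao_mean,74,mmHg,table2,0
cs,P0,2500,p_ao_mean,85,mmHg,table2,0
cs,P0,3000,p_ao_mean,97,mmHg,table2,0
cs,P0,0,p_vr_mean,15.0,mmHg,table2,0
cs,P0,1000,p_vr_mean,13.1,mmHg,table2,0
cs,P0,1500,p_vr_mean,11.1,mmHg,table2,0
cs,P0,2000,p_vr_mean,9.7,mmHg,table2,0
cs,P0,2500,p_vr_mean,8.1,mmHg,table2,0
cs,P0,3000,p_vr_mean,7.0,mmHg,table2,0
cs,P0,0,peak_lvp,88,mmHg,table2,0
cs,P0,1000,peak_lvp,86,mmHg,table2,0
cs,P0,1500,peak_lvp,92,mmHg,table2,0
cs,P0,2000,peak_lvp,98,mmHg,table2,0
cs,P0,2500,peak_lvp,105,mmHg,table2,0
cs,P0,3000,peak_lvp,112,mmHg,table2,0
cs,P0,0,edp,24,mmHg,table2,0
cs,P0,1000,edp,24,mmHg,table2,0
cs,P0,1500,edp,27,mmHg,table2,0
cs,P0,2000,edp,31,mmHg,table2,0
cs,P0,2500,edp,35,mmHg,table2,0
cs,P0,3000,edp,51,mmHg,table2,0
cs,P0,0,esv,148,ml,table2,0
cs,P0,1000,esv,148,ml,table2,0
cs,P0,1500,esv,152,ml,table2,0
cs,P0,2000,esv,200,ml,table2,1
cs,P0,2500,esv,171,ml,table2,0
cs,P0,3000,esv,189,ml,table2,0
cs,P0,0,edv,199,ml,table2,0
cs,P0,1000,edv,200,ml,table2,0
cs,P0,1500,edv,201,ml,table2,0
cs,P0,2000,edv,201,ml,table2,0
cs,P0,2500,edv,202,ml,table2,0
cs,P0,3000,edv,204,ml,table2,0
cs,P0,0,sv,51,ml,table2,0
cs,P0,1000,sv,52,ml,table2,0
cs,P0,1500,sv,46,ml,table2,0
cs,P0,2000,sv,42,ml,table2,0
cs,P0,2500,sv,31,ml,table2,0
cs,P0,3000,sv,15,ml,table2,0
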