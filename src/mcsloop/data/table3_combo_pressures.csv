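condition,impella_level,ecmo_rpm,quantity,value,unit,source,anomaly
cs,P0,0,total_flow,2.7,L/min,table3,0
cs,P2,0,total_flow,3.64,L/min,table3,0
cs,P4,0,total_flow,3.82,L/min,table3,0
cs,P6,0,total_flow,3.96,L/min,table3,0
cs,P8,0,total_flow,4.14,L/min,table3,0
cs,P0,0,p_ao_sys,73,mmHg,table3,0
cs,P2,0,p_ao_sys,82,mmHg,table3,0
cs,P4,0,p_ao_sys,84,mmHg,table3,0
cs,P6,0,p_ao_sys,86,mmHg,table3,0
cs,P8,0,p_ao_sys,90,mmHg,table3,0
cs,P0,0,p_ao_dia,23,mmHg,table3,0
cs,P2,0,p_ao_dia,48,mmHg,table3,0
cs,P4,0,p_ao_dia,55,mmHg,table3,0
cs,P6,0,p_ao_dia,59,mmHg,table3,0
cs,P8,0,p_ao_dia,63,mmHg,table3,0
cs,P0,0,p_ao_mean,46,mmHg,table3,0
cs,P2,0,p_ao_mean,64,mmHg,table3,0
cs,P4,0,p_ao_mean,68,mmHg,table3,0
cs,P6,0,p_ao_mean,71,mmHg,table3,0
cs,P8,0,p_ao_mean,74,mmHg,table3,0
cs,P0,0,p_vr_mean,15.0,mmHg,table3,0
cs,P2,0,p_vr_mean,11.3,mmHg,table3,0
cs,P4,0,p_vr_mean,10.5,mmHg,table3,0
cs,P6,0,p_vr_mean,10.0,mmHg,table3,0
cs,P8,0,p_vr_mean,9.3,mmHg,table3,0
cs,P0,2000,total_flow,3.99,L/min,table3,0
cs,P2,2000,total_flow,4.26,L/min,table3,0
cs,P4,2000,total_flow,4.37,L/min,table3,0
cs,P6,2000,total_flow,4.54,L/min,table3,0
cs,P8,2000,total_flow,4.71,L/min,table3,0
cs,P0,2000,p_ao_sys,88,mmHg,table3,0
cs,P2,2000,p_ao_sys,92,mmHg,table3,0
cs,P4,2000,p_ao_sys,93,mmHg,table3,0
cs,P6,2000,p_ao_sys,96,mmHg,table3,0
cs,P8,2000,p_ao_sys,98,mmHg,table3,0
cs,P0,2000,p_ao_dia,61,mmHg,table3,0
cs,P2,2000,p_ao_dia,69,mmHg,table3,0
cs,P4,2000,p_ao_dia,72,mmHg,table3,0
cs,P6,2000,p_ao_dia,79,mmHg,table3,0
cs,P8,2000,p_ao_dia,83,mmHg,table3,0
cs,P0,2000,p_ao_mean,74,mmHg,table3,0
cs,P2,2000,p_ao_mean,79,mmHg,table3,0
cs,P4,2000,p_ao_mean,81,mmHg,table3,0
cs,P6,2000,p_ao_mean,86,mmHg,table3,0
cs,P8,2000,p_ao_mean,89,mmHg,table3,0
cs,P0,2000,p_vr_mean,9.7,mmHg,table3,0
cs,P2,2000,p_vr_mean,8.1,mmHg,table3,0
cs,P4,2000,p_vr_mean,8.3,mmHg,table3,0
cs,P6,2000,p_vr_mean,7.6,mmHg,table3,0
cs,P8,2000,p_vr_mean,7.3,mmHg,table3,0
cs,P0,3000,total_flow,4.47,L/min,table3,0
cs,P2,3000,total_flow,4.69,L/min,table3,0
cs,P4,3000,total_flow,4.69,L/min,table3,0
cs,P6,3000,total_flow,4.78,L/min,table3,0
cs,P8,3000,total_flow,5.24,L/min,table3,0
cs,P0,3000,p_ao_sys,106,mmHg,table3,0
cs,P2,3000,p_ao_sys,108,mmHg,table3,0
cs,P4,3000,p_ao_sys,109,mmHg,table3,0
cs,P6,3000,p_ao_sys,110,mmHg,table3,0
cs,P8,3000,p_ao_sys,120,mmHg,table3,0
cs,P0,3000,p_ao_dia,91,mmHg,table3,0
cs,P2,3000,p_ao_dia,96,mmHg,table3,0
cs,P4,3000,p_ao_dia,97,mmHg,table3,0
cs,P6,3000,p_ao_dia,101,mmHg,table3,0
cs,P8,3000,p_ao_dia,114,mmHg,table3,0
cs,P0,3000,p_ao_mean,97,mmHg,table3,0
cs,P2,3000,p_ao_mean,101,mmHg,table3,0
cs,P4,3000,p_ao_mean,102,mmHg,table3,0
cs,P6,3000,p_ao_mean,105,mmHg,table3,0
cs,P8,3000,p_ao_mean,116,mmHg,table3,0
cs,P0,3000,p_vr_mean,7.0,mmHg,table3,0
cs,P2,3000,p_vr_mean,6.1,mmHg,table3,0
cs,P4,3000,p_vr_mean,6.3,mmHg,table3,0
cs,P6,3000,p_vr_mean,6.0,mmHg,table3,0
cs,P8,3000,p_vr_mean,5.0,mmHg,table3,0
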