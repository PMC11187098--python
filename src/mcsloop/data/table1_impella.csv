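condition,impella_level,ecmo_rpm,quantity,value,unit,source,anomaly
cs,P0,0,total_flow,2.7,L/min,table1,0
cs,P1,0,total_flow,3.27,L/min,table1,0
cs,P2,0,total_flow,3.64,L/min,table1,0
cs,P3,0,total_flow,3.7,L/min,table1,0
cs,P4,0,total_flow,3.82,L/min,table1,0
cs,P5,0,total_flow,3.89,L/min,table1,0
cs,P6,0,total_flow,3.96,L/min,table1,0
cs,P7,0,total_flow,4.07,L/min,table1,0
cs,P8,0,total_flow,4.14,L/min,table1,0
cs,P9,0,total_flow,4.18,L/min,table1,0
cs,P0,0,p_ao_sys,73,mmHg,table1,0
cs,P1,0,p_ao_sys,78,mmHg,table1,0
cs,P2,0,p_ao_sys,82,mmHg,table1,0
cs,P3,0,p_ao_sys,83,mmHg,table1,0
cs,P4,0,p_ao_sys,84,mmHg,table1,0
cs,P5,0,p_ao_sys,85,mmHg,table1,0
cs,P6,0,p_ao_sys,86,mmHg,table1,0
cs,P7,0,p_ao_sys,88,mmHg,table1,0
cs,P8,0,p_ao_sys,90,mmHg,table1,0
cs,P9,0,p_ao_sys,91,mmHg,table1,0
cs,P0,0,p_ao_dia,23,mmHg,table1,0
cs,P1,0,p_ao_dia,39,mmHg,table1,0
cs,P2,0,p_ao_dia,48,mmHg,table1,0
cs,P3,0,p_ao_dia,52,mmHg,table1,0
cs,P4,0,p_ao_dia,55,mmHg,table1,0
cs,P5,0,p_ao_dia,57,mmHg,table1,0
cs,P6,0,p_ao_dia,59,mmHg,table1,0
cs,P7,0,p_ao_dia,61,mmHg,table1,0
cs,P8,0,p_ao_dia,63,mmHg,table1,0
cs,P9,0,p_ao_dia,65,mmHg,table1,0
cs,P0,0,p_ao_mean,46,mmHg,table1,0
cs,P1,0,p_ao_mean,56,mmHg,table1,0
cs,P2,0,p_ao_mean,64,mmHg,table1,0
cs,P3,0,p_ao_mean,66,mmHg,table1,0
cs,P4,0,p_ao_mean,68,mmHg,table1,0
cs,P5,0,p_ao_mean,69,mmHg,table1,0
cs,P6,0,p_ao_mean,71,mmHg,table1,0
cs,P7,0,p_ao_mean,73,mmHg,table1,0
cs,P8,0,p_ao_mean,74,mmHg,table1,0
cs,P9,0,p_ao_mean,76,mmHg,table1,0
cs,P0,0,p_vr_mean,15.0,mmHg,table1,0
cs,P1,0,p_vr_mean,12.3,mmHg,table1,0
cs,P2,0,p_vr_mean,11.3,mmHg,table1,0
cs,P3,0,p_vr_mean,10.9,mmHg,table1,0
cs,P4,0,p_vr_mean,10.5,mmHg,table1,0
cs,P5,0,p_vr_mean,10.4,mmHg,table1,0
cs,P6,0,p_vr_mean,10.0,mmHg,table1,0
cs,P7,0,p_vr_mean,9.4,mmHg,table1,0
cs,P8,0,p_vr_mean,9.3,mmHg,table1,0
cs,P9,0,p_vr_mean,9.1,mmHg,table1,0
cs,P0,0,peak_lvp,88,mmHg,table1,0
cs,P1,0,peak_lvp,87,mmHg,table1,0
cs,P2,0,peak_lvp,90,mmHg,table1,0
cs,P3,0,peak_lvp,91,mmHg,table1,0
cs,P4,0,peak_lvp,92,mmHg,table1,0
cs,P5,0,peak_lvp,92,mmHg,table1,0
cs,P6,0,peak_lvp,92,mmHg,table1,0
cs,P7,0,peak_lvp,94,mmHg,table1,0
cs,P8,0,peak_lvp,95,mmHg,table1,0
cs,P9,0,peak_lvp,95,mmHg,table1,0
cs,P0,0,edp,24,mmHg,table1,0
cs,P1,0,edp,21,mmHg,table1,0
cs,P2,0,edp,20,mmHg,table1,0
cs,P3,0,edp,20,mmHg,table1,0
cs,P4,0,edp,18,mmHg,table1,0
cs,P5,0,edp,18,mmHg,table1,0
cs,P6,0,edp,18,mmHg,table1,0
cs,P7,0,edp,17,mmHg,table1,0
cs,P8,0,edp,18,mmHg,table1,0
cs,P9,0,edp,17,mmHg,table1,0
cs,P0,0,esv,148,ml,table1,0
cs,P1,0,esv,157,ml,table1,0
cs,P2,0,esv,155,ml,table1,0
cs,P3,0,esv,156,ml,table1,0
cs,P4,0,esv,156,ml,table1,0
cs,P5,0,esv,154,ml,table1,0
cs,P6,0,esv,150,ml,table1,0
cs,P7,0,esv,147,ml,table1,0
cs,P8,0,esv,147,ml,table1,0
cs,P9,0,esv,148,ml,table1,0
cs,P0,0,edv,199,ml,table1,0
cs,P1,0,edv,210,ml,table1,0
cs,P2,0,edv,204,ml,table1,0
cs,P3,0,edv,199,ml,table1,0
cs,P4,0,edv,203,ml,table1,0
cs,P5,0,edv,193,ml,table1,0
cs,P6,0,edv,188,ml,table1,0
cs,P7,0,edv,187,ml,table1,0
cs,P8,0,edv,184,ml,table1,0
cs,P9,0,edv,180,ml,table1,0
cs,P0,0,sv,51,ml,table1,0
cs,P1,0,sv,53,ml,table1,0
cs,P2,0,sv,50,ml,table1,0
cs,P3,0,sv,42,ml,table1,0
cs,P4,0,sv,47,ml,table1,0
cs,P5,0,sv,39,ml,table1,0
cs,P6,0,sv,38,ml,table1,0
cs,P7,0,sv,40,ml,table1,0
cs,P8,0,sv,37,ml,table1,0
cs,P9,0,sv,32,ml,table1,0
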