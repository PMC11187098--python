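condition,impella_level,ecmo_rpm,quantity,value,unit,source,anomaly
cs,P0,0,q_aorta,2.28,L/min,table4,0
cs,P2,0,q_aorta,3.03,L/min,table4,0
cs,P4,0,q_aorta,3.21,L/min,table4,0
cs,P6,0,q_aorta,3.34,L/min,table4,0
cs,P8,0,q_aorta,3.47,L/min,table4,0
cs,P0,0,q_iliac,2.33,L/min,table4,0
cs,P2,0,q_iliac,3.14,L/min,table4,0
cs,P4,0,q_iliac,3.3,L/min,table4,0
cs,P6,0,q_iliac,3.41,L/min,table4,0
cs,P8,0,q_iliac,3.57,L/min,table4,0
cs,P0,0,q_brachio,0.38,L/min,table4,0
cs,P2,0,q_brachio,0.5,L/min,table4,0
cs,P4,0,q_brachio,0.53,L/min,table4,0
cs,P6,0,q_brachio,0.55,L/min,table4,0
cs,P8,0,q_brachio,0.57,L/min,table4,0
cs,P0,0,total_flow,2.7,L/min,table4,0
cs,P2,0,total_flow,3.64,L/min,table4,0
cs,P4,0,total_flow,3.82,L/min,table4,0
cs,P6,0,total_flow,3.96,L/min,table4,0
cs,P8,0,total_flow,4.14,L/min,table4,0
cs,P0,2000,q_aorta,1.41,L/min,table4,0
cs,P2,2000,q_aorta,1.63,L/min,table4,0
cs,P4,2000,q_aorta,1.82,L/min,table4,0
cs,P6,2000,q_aorta,2.16,L/min,table4,0
cs,P8,2000,q_aorta,2.37,L/min,table4,0
cs,P0,2000,q_iliac,3.47,L/min,table4,0
cs,P2,2000,q_iliac,3.67,L/min,table4,0
cs,P4,2000,q_iliac,3.77,L/min,table4,0
cs,P6,2000,q_iliac,3.92,L/min,table4,0
cs,P8,2000,q_iliac,4.05,L/min,table4,0
cs,P0,2000,q_brachio,0.52,L/min,table4,0
cs,P2,2000,q_brachio,0.59,L/min,table4,0
cs,P4,2000,q_brachio,0.6,L/min,table4,0
cs,P6,2000,q_brachio,0.62,L/min,table4,0
cs,P8,2000,q_brachio,0.67,L/min,table4,0
cs,P0,2000,total_flow,3.99,L/min,table4,0
cs,P2,2000,total_flow,4.26,L/min,table4,0
cs,P4,2000,total_flow,4.37,L/min,table4,0
cs,P6,2000,total_flow,4.54,L/min,table4,0
cs,P8,2000,total_flow,4.72,L/min,table4,0
cs,P0,3000,q_aorta,-0.27,L/min,table4,0
cs,P2,3000,q_aorta,-0.05,L/min,table4,0
cs,P4,3000,q_aorta,-0.1,L/min,table4,0
cs,P6,3000,q_aorta,0.07,L/min,table4,0
cs,P8,3000,q_aorta,0.6,L/min,table4,0
cs,P0,3000,q_iliac,3.85,L/min,table4,0
cs,P2,3000,q_iliac,4.0,L/min,table4,0
cs,P4,3000,q_iliac,4.0,L/min,table4,0
cs,P6,3000,q_iliac,4.08,L/min,table4,0
cs,P8,3000,q_iliac,4.46,L/min,table4,0
cs,P0,3000,q_brachio,0.63,L/min,table4,0
cs,P2,3000,q_brachio,0.69,L/min,table4,0
cs,P4,3000,q_brachio,0.69,L/min,table4,0
cs,P6,3000,q_brachio,0.7,L/min,table4,0
cs,P8,3000,q_brachio,0.77,L/min,table4,0
cs,P0,3000,total_flow,4.47,L/min,table4,0
cs,P2,3000,total_flow,4.69,L/min,table4,0
cs,P4,3000,total_flow,4.69,L/min,table4,0
cs,P6,3000,total_flow,4.78,L/min,table4,0
cs,P8,3000,total_flow,5.24,L/min,table4,0
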