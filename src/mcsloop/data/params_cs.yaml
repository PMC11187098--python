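condition: cs
circuit:
  r_systemic_mmHg_s_per_ml: 0.15490876777658782
  k_systemic_mmHg_s2_per_ml2: 0.013967167938469678
  r_brachio_mmHg_s_per_ml: 1.0783911294945616
  k_brachio_mmHg_s2_per_ml2: 0.7269614205748652
  r_aortic_seg_mmHg_s_per_ml: 0.025505846909361224
  l_aortic_mmHg_s2_per_ml: 0.0
  c_venous_ml_per_mmHg: 13.23944077939637
  c_distal_ml_per_mmHg: 0.3
  aortic_beta: 6.0
  aortic_ref_pressure_mmHg: 100.0
  aortic_ref_volume_ml: 141.93867864345626
  v_unstressed_art_ml: 0.0
  v_unstressed_dist_ml: 50.0
  v_unstressed_ven_ml: 2800.0
  v_total_ml: 3317.0857923350086
elastance:
  e_max_mmHg_per_ml: 0.7308599052090253
  e_min_mmHg_per_ml: 0.08237343407319364
  v0_ml: 71.43359820515519
  t_sys_frac: 0.20075818768336787
  hr_bpm: 75.0
valves:
  mitral_r_mmHg_s_per_ml: 0.01
  aortic_r_mmHg_s_per_ml: 0.03807597768626739
  smoothing_mmHg: 0.3
suction_guard:
  threshold_mmHg: 2.0
  floor_mmHg: -5.0
impella:
  c_speed_mmHg_per_rpm2: 6.903122673267773e-08
  c_flow_mmHg_s2_per_ml2: 0.02339522407883981
  r_cannula_mmHg_s_per_ml: 0.04992029074558473
  q_max_mean_L_per_min: 3.7
ecmo:
  c_speed_mmHg_per_rpm2: 3.020846260244362e-05
  c_flow_mmHg_s2_per_ml2: 0.02308286362645675
  r_circuit_mmHg_s_per_ml: 0.21835416630077994
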