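a_ca: 1.0
a_cyt: 2.6
a_mit: 5.0
atp_per_glc: 2.0
c_mito: 0.02
demand_fractions:
  high: 0.85
  intermediate: 0.45
  low: 0.1
f_mit: 1.0
fadh2_per_pyr: 1.0
henry_o2_um_per_mmhg: 1.3
k_demand:
  high: 0.658029
  intermediate: 0.348368
  low: 0.077415
k_ldh: 500.0
k_leak: 0.0001
keq_ldh: 10000.0
km_ant_adp: 0.1
km_ant_atp: 0.5
km_atp: 0.1
km_c1: 0.1
km_c2: 0.05
km_ca: 0.5
km_g3p_fad: 0.1
km_g3p_nadh: 0.01
km_glut: 7.0
km_gly_adp: 0.3
km_gly_atp: 0.1
km_gly_glc: 0.2
km_gly_nad: 0.05
km_mas_nad: 0.2
km_mas_nadh: 0.01
km_mct: 1.0
km_ncx: 1.0
km_o2: 0.5
km_syn_adp: 0.3
km_tca_fad: 0.05
km_tca_nad: 0.2
km_tca_pyr: 0.02
n_cyt: 0.5
n_h_c1: 10.0
n_h_c2: 6.0
n_h_syn: 3.0
n_mit: 2.0
nadh_per_glc: 2.0
nadh_per_pyr: 4.0
o2_per_equiv: 0.5
ph_cyt: 7.0
ph_frac: 0.2
pmf_pump: 185.0
pmf_syn: 100.0
psi_uni: 150.0
s_uni: 20.0
slope_pump: 10.0
slope_syn: 15.0
tau_ph: 1.0
turnover_max: 0.774152
v_ant: 3.0
v_c1: 0.9
v_c2: 0.3
v_g3p: 0.08
v_glut: 0.07
v_gly: 0.5
v_mas: 0.4
v_mct: 0.0688
v_ncx: 0.1
v_syn: 2.0
v_tca: 0.4
v_uni: 0.05
z_ph: 61.5
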