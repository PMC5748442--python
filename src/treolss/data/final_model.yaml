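# Final pediatric treosulfan population-PK model.
# Typical values referenced to 70 kg; IIV as SDs of log-scale random effects;
# corr_cl_v1 is the correlation between eta_Cl and eta_V1; residual error is
# proportional-only. Units: L/h, L, h, mg, mg/L.
theta:
  cl: 14.7
  v1: 26.0
  q: 2.25
  v2: 9.93
beta:
  cl: 0.75
  v1: 1.0
  q: 0.0      # bodyweight worsened the fit for Q; not scaled
  v2: 1.0
ref_weight: 70.0
omega:
  cl: 0.255
  v1: 0.514
  q: 0.386
corr_cl_v1: 0.714
prop_error_b: 0.188
add_error: 0.0
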