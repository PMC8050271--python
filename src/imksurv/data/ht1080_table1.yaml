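# Fitted model parameters for the HT1080 fibrosarcoma line under 150 kVp
# X-rays with 4-MU, with fitting errors (s.d.).  gamma is the tabulated
# microdosimetric value; it is reproduced by the spherical-domain
# conversion from y_d to ~0.1%.
s_p_min: 0.0003
s_p_max: 1.000
ed50: 92.07          # uM
r_p: 1.637
y_d: 4.683           # keV/um
domain_diameter: 1.0 # um
gamma: 0.954         # Gy
alpha0: 0.053        # /Gy
beta0: 0.069         # /Gy^2
a_plus_c: 2.215      # /h
alpha_b: 0.010       # /Gy
beta_b: 0.032        # /Gy^2
delta_min: 0.760
delta_max: 8.175
r_delta: 8.816
std_errors:
  s_p_min: 0.0002
  ed50: 1.797
  r_p: 0.012
  y_d: 0.050
  gamma: 0.011
  alpha0: 0.028
  beta0: 0.004
  a_plus_c: 0.007
  alpha_b: 0.006
  beta_b: 0.018
  delta_min: 0.016
  delta_max: 0.001
  r_delta: 0.011
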