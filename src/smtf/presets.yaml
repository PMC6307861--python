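# Kinetic parameter presets for the synthetic-data generator.
#
# f_bound / tau_res_s / frap_t_half_slow_s encode the measured values for
# each protein class; diffusion coefficients and the non-specific off-rate
# are implementation defaults chosen as field-realistic (the source imaging
# study does not print them in its text).
zld_like:
  f_bound: 0.5
  tau_res_s: 5.56          # specific residence time; k_off_specific = 1/tau
  k_off_nonspecific: 2.0   # 1/s
  f_specific: 0.5          # fraction of bound molecules in the specific class
  d_bound: 0.01            # um^2/s
  d_free: 3.0              # um^2/s
  frap_t_half_slow_s: 5.0

bcd_like:
  f_bound: 0.5
  tau_res_s: 2.33
  k_off_nonspecific: 2.0
  f_specific: 0.5
  d_bound: 0.01
  d_free: 3.0
  frap_t_half_slow_s: 1.0

his2b_like:
  f_bound: 0.88
  tau_res_s: .inf          # the specific (histone) class never unbinds
  k_off_nonspecific: 2.0
  f_specific: 1.0
  d_bound: 0.01
  d_free: 3.0
  frap_t_half_slow_s: .inf
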