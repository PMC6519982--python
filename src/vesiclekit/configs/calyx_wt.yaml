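# WT-like calyx of Held parameter set.
# Printed / protocol-anchored values: 300 Hz x 300 ms (90 APs); steady-state
# release ~53-59 quanta/AP; alpha_0 = 5.4/s at rest onset; ss window 150-300 ms.
# Implementer-chosen values (documented in docs/methods.md): site counts and
# class pv values (rested mean pv 0.34, mostly-high composition; capacity 3200
# so that RRP estimates stay below half of the ~7000 quanta per train), alpha_inf,
# tau_alpha, alpha_train (sets the ~53 quanta/AP steady state), quantal size.
label: calyx_wt
mode: both
seed: 7
n_sweeps: 20
model:
  n_high: 2880
  n_low: 320
  pv_high: 0.36
  pv_low: 0.12
  alpha_0: 5.4        # printed
  alpha_inf: 1.5
  tau_alpha: 2.0
  alpha_train: 5.0
  facilitation_increment: 0.0
  facilitation_tau: 0.1
  quantal_size: 0.1   # pC
  quantal_cv: 0.3
  mini_rate: 10.0
  rest_threshold: 0.1
protocols:
  - segments: [[300, 90]]   # printed protocol
    label: "300Hz x 300ms"
estimator:
  preparation: calyx
  ss_window: [0.15, 0.30]   # printed window
  alpha: 5.0
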