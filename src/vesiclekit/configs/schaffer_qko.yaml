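# QKO-like Schaffer collateral: schaffer_wt with both class pv values doubled.
label: schaffer_qko
mode: both
seed: 7
n_sweeps: 20
model:
  n_high: 200
  n_low: 200
  pv_high: 0.4        # 2x WT
  pv_low: 0.1         # 2x WT
  alpha_0: 0.5
  alpha_inf: 0.1
  tau_alpha: 2.0
  alpha_train: 0.25
  facilitation_increment: 0.45
  facilitation_tau: 0.1
  quantal_size: 0.05
  quantal_cv: 0.3
  mini_rate: 2.0
  rest_threshold: 0.1
protocols:
  - segments: [[20, 120]]
    label: "20Hz x 6s"
estimator:
  preparation: schaffer
  alpha: 0.25
fm:
  stained_fraction_rrp: 0.5
  stained_fraction_reserve: 0.5
  rundown_slope: -0.02
  background_level: 100.0
  f_inf_level: 20.0
  noise_sd: 0.5
  frame_interval: 4.0
  n_rois: 250
  pv_scatter: 0.2
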