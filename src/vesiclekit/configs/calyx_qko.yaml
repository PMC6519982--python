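# QKO-like calyx of Held: identical to calyx_wt except both class pv values
# doubled (the genotype's sole effect in this model); everything else as in
# calyx_wt.yaml.
label: calyx_qko
mode: both
seed: 7
n_sweeps: 20
model:
  n_high: 2880
  n_low: 320
  pv_high: 0.72        # 2x WT
  pv_low: 0.24         # 2x WT
  alpha_0: 5.4        # printed
  alpha_inf: 1.5
  tau_alpha: 2.0
  alpha_train: 5.0
  facilitation_increment: 0.0
  facilitation_tau: 0.1
  quantal_size: 0.1
  quantal_cv: 0.3
  mini_rate: 10.0
  rest_threshold: 0.1
protocols:
  - segments: [[300, 90]]
    label: "300Hz x 300ms"
estimator:
  preparation: calyx
  ss_window: [0.15, 0.30]
  alpha: 5.0
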