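# Default study design: two groups of n = 4 mice, 5 min baseline / 200 s
# inhalation / 15 min washout sampled every 18.2 s, full model-comparison
# grid (linear and three-phase at alpha = 0.7 / 0.5, Tc -> 0 / 3 s).
# Group truths are the three-phase (Tc = 3 s, alpha = 0.7) fitted values
# for wild-type controls (CTR) and APPswe/PS1dE9 transgenics (APP), with
# the reported between-subject spreads.
seed: 0
protocol:
  t_baseline_s: 300.0
  t_inhale_s: 200.0
  t_washout_s: 900.0
  frame_dt_s: 18.2
  alpha: 0.7
  tc_s: 3.0
noise:
  sigma: 0.5
  distribution: gaussian
groups:
  - label: CTR
    n_subjects: 4
    mean: {cmro2: 2.02, k_g: 0.62, k_l: 0.39}
    sd: {cmro2: 0.10, k_g: 0.18, k_l: 0.04}
  - label: APP
    n_subjects: 4
    mean: {cmro2: 1.68, k_g: 0.45, k_l: 0.36}
    sd: {cmro2: 0.14, k_g: 0.06, k_l: 0.06}
models:
  - {name: linear, alpha: 0.7}
  - {name: three_phase, alpha: 0.7, tc_s: 0.0001}
  - {name: three_phase, alpha: 0.7, tc_s: 3.0}
  - {name: linear, alpha: 0.5}
  - {name: three_phase, alpha: 0.5, tc_s: 0.0001}
  - {name: three_phase, alpha: 0.5, tc_s: 3.0}
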