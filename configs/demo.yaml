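# Desk-scale demonstration study: small enough to run in about a minute on
# one CPU, structurally identical to the full design (two groups, four
# longitudinal sessions, one stimulated ear, four pooled comprehension
# conditions with a late 600-1200 ms signal window).
seed: 2024
out_dir: results/run
study:
  n_subjects_per_group: 6
  n_channels: 24
  trials_per_condition: 24
  effect_scale: 1.3
  ears_implanted: [non-CI]
  cross_group_similarity:
    pre-op: 0.0
    3m: 0.45
    6m: 0.7
    12m: 0.9
preprocess:
  z_threshold: 100.0
  sobi: false
decoding:
  n_iter: 16
  dt_ms: 20.0
  time_range: [-500.0, 1500.0]
rsa:
  window_ms: [600.0, 1200.0]
stats:
  n_perm: 1000
  cluster_alpha: 0.05
  alpha: 0.05
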