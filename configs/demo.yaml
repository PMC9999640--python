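# End-to-end demo configuration for `ecgrt run --config configs/demo.yaml`.
# Every block mirrors a config dataclass; omitted keys keep their defaults.

seed: 1

cohort:
  groups:
    negative: {count: 47}
    normal:   {count: 4,  ischemia_mean: 0.8, ischemia_sd: 0.10}
    lt50:     {count: 14, ischemia_mean: 1.5, ischemia_sd: 0.15}
    ge50:     {count: 8,  ischemia_mean: 2.6, ischemia_sd: 0.20}
  duration: 17.0
  sampling_rate: 250.0

preprocess:
  leadin_s: 7.0
  window_s: 10.0
  baseline_cutoff: 0.5
  notch_freq: 60.0

sift:
  stop_threshold: 0.2
  max_imfs: 8

weights:
  alpha: 0.5
  beta: 0.3
  gamma: 0.15

stats:
  models: [1, 2, 3]
  ci_level: 0.95
  variance_policy: welch
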