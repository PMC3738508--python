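# Example end-to-end pipeline configuration (mouse model, small cohort).
seed: 1
preset: mouse
n_per_group: 3
log_level: INFO
synth:
  image_size: 256
  n_sections: 4
segmentation:
  mu: 0.02
quantify:
  closing_radius: 12
  tuft_q: 0.95
smia:
  k: 5
  record_every: 5
  peripheral_fraction: 0.55
stats:
  alpha: 0.05
  pca_var_target: 0.9
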