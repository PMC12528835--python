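# Default desk-scale pipeline configuration.
# Every stochastic stage draws from an explicit named seed.

seeds:
  cohort: 11
  decode: 12
  inference: 13

out_dir: svdecode_out

cohort:
  n_per_group: 5
  group_labels: [control, oud]
  missing_rate: 0.02

signal:
  amplitude: 1.5
  # silence group-specific networks, e.g. to emulate a less distributed
  # representation in the second group:
  amplitude_overrides:
    oud:
      limbic: 0.0
      salience/ventral-attention: 0.0
  shared_across_contexts: 1.0
  noise_sd: 1.0
  rois_per_network: 2
  voxels_per_roi: [12, 20]

decode:
  n_boot: 20
  C: 1.0
  split_kind: overall
  exclude_catch: false

inference:
  n_perm: 200
  thresholds: [0.05, 0.01, 0.001]
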