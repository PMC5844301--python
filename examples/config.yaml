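# Example replication-experiment configuration (defaults shown explicitly).
# Any key may be omitted; see pipeline.RunConfig and simpop.DemographyConfig.
demography:
  n_per_subpop: 8
  L: 1100000
  mu: 1.25e-07
  theta_neutral: 0.005
  split_depths:
    aus: 2000.0
    indica: 2000.0
    japonica: 2000.0
    OrI_internal: 9000.0
    OrIII_OrI: 15000.0
    OrII: 25000.0
  bottleneck_factor: 0.1
  sweep_interval: [480000, 520000]
  post_sweep_time: 100.0
  block_length: 5000
  chrom: chr1
  seed: 1
mean_depth: 2.0
error_rate: 0.001
window_sizes: [20000]
percentile: 97.5
flank_sizes: [20000, 500000]
n_replicates: 20
seed: 1
sweep: true
n_concat_neutral: 50
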