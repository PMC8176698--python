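core_threshold: 0.75
do_assembly: true
do_networks: true
do_random_graphs: false
filter_min_samples: 5
filter_min_total_reads: 10
filter_mode: conjunctive
input_metadata: null
input_table: null
input_taxonomy: null
n_permutations: 199
n_random_graphs: 1000
n_swap_samples: 2000
network_min_samples: 10
network_min_total_reads: 50
network_subsets:
- all
p_threshold: 0.01
pi_threshold: 0.62
r_threshold: 0.6
rarefaction_depth: 146973
rarefy_to_min: true
robustness_fractions:
- 0.0
- 0.05
- 0.1
- 0.15
- 0.2
- 0.25
- 0.3
- 0.35
- 0.4
- 0.45
- 0.5
- 0.55
- 0.6
- 0.65
- 0.7
- 0.75
- 0.8
robustness_reps: 30
salinity_breaks:
- 0.2
- 2.0
satellite_threshold: 0.5
seed: 11
sparcc_exclusion_rounds: 10
sparcc_exclusion_threshold: 0.8
sparcc_inner_iter: 10
sparcc_n_boot: 50
swap_thin: 1
synthetic:
  N: 2000
  S: 120
  cadence_days: 3.5
  lognormal_sigma: 1.5
  m: 0.15
  n_samples: 60
  salinity_profile: seasonal
  salinity_range:
  - 0.0
  - 6.1
  selection_sigma: 1.0
  selection_strength: 3.0
zi_threshold: 2.5
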