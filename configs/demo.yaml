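# Demonstration pipeline: synthetic double-well umbrella windows -> WHAM PMF,
# reference contribution-table ledger assembly, and the salt regression.
temperature: 300.0
seed: 12345
output_dir: pipeline_output
stages: [generate, estimate, ledger, fits]
generate:
  potential: double_well
  centers_start: -1.6
  centers_stop: 1.6
  n_windows: 11
  k_bias: 10.0
  convention: full
  n_per_window: 3000
  step_size: 0.3
estimate:
  bin_width: 0.1
  tol: 1.0e-7
  max_iter: 100000
  n_error_blocks: 10
ledger:
  water_model: TIP3P
  salt_mM: 81
fits:
  salt_log_base: natural
  interpolate_at: -12.2
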