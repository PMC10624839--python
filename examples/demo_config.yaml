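# Demo pipeline configuration for `neuromux report --config examples/demo_config.yaml`.
# Values omitted here fall back to the study-condition defaults
# (104 neurons, 80 trials/stimulus, 200 permutations).
seed: 1
session:
  n_trials_per_stimulus: 40
  n_neurons: 24
  effect_gain: 10.0
  decay_tau_early: 1.5
images:
  width: 96
  height: 96
analysis:
  n_permutations: 50
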