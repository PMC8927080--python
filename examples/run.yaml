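# Full-pipeline configuration: simulate a small cohort and run every stage.
source:
  simulate:
    n_subjects: 2
    trials_per_subject: 2
    trial_duration: 30.0
    neural_rate_hz: 1000.0
    n_strip_contacts: 2
    n_depth_contacts: 2
    fog_episodes_per_trial: 1
    fog_duration_range: [6.0, 9.0]
stages:
  screen: true
  gait_summary: true
  fi: true
  bandpower: true
  coherence: true
  classify: true
params:
  bandpower:
    # restrict the Morlet grid to the beta range for a quick run
    frequencies: [13.98, 16.06, 18.45, 21.19, 24.35, 27.98, 32.14]
  coherence:
    n_surrogates: 400
    surrogate_method: segment_shuffle
  classify:
    n_permutations: 100
    n_estimators: 64
    max_iter: 3
output_dir: scratch/run_output
seed: 1
log_level: WARNING
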