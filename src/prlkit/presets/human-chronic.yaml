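# Between-group chronic SSRI in humans. The emulated study's group sizes are
# not stated in the available text; 32 vs 33 (the acute study's sizes) stand
# in. Treatment signature: lower reinforcement sensitivity only.
name: human-chronic
task: human
task_config:
  n_trials: 80
  p_good: 0.8
  reversal_trial: 40
design: between
model: M2_rp_stick
groups:
  - label: placebo
    n_subjects: 33
    means_natural: {alpha_rew: 0.25, alpha_pun: 0.45, tau_reinf: 3.0, tau_stick: 0.5}
    sds_unconstrained: {alpha_rew: 0.4, alpha_pun: 0.4, tau_reinf: 0.4, tau_stick: 0.4}
  - label: ssri-chronic
    n_subjects: 32
    means_natural: {alpha_rew: 0.25, alpha_pun: 0.45, tau_reinf: 1.5, tau_stick: 0.5}
    sds_unconstrained: {alpha_rew: 0.4, alpha_pun: 0.4, tau_reinf: 0.4, tau_stick: 0.4}
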