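# Between-group repeated SSRI (7 treated vs 7 vehicle rats).
# Treatment signature: higher punishment learning rate and higher stickiness.
name: rat-repeated
task: rat
task_config:
  n_trials_per_session: 200
  n_sessions: 5
  p_good: 0.8
  reversal_criterion: 8
design: between
model: M2_rp_stick
groups:
  - label: vehicle
    n_subjects: 7
    means_natural: {alpha_rew: 0.25, alpha_pun: 0.45, tau_reinf: 3.0, tau_stick: 0.5}
    sds_unconstrained: {alpha_rew: 0.4, alpha_pun: 0.4, tau_reinf: 0.4, tau_stick: 0.4}
  - label: ssri-repeated
    n_subjects: 7
    means_natural: {alpha_rew: 0.25, alpha_pun: 0.65, tau_reinf: 3.0, tau_stick: 0.66}
    sds_unconstrained: {alpha_rew: 0.4, alpha_pun: 0.4, tau_reinf: 0.4, tau_stick: 0.4}
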