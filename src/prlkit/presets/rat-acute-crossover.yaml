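# Within-subject cross-over: 11 rats under vehicle, low-dose and high-dose
# acute SSRI. Low dose: lower stickiness, higher reward learning rate.
# High dose: lower reward learning rate, higher reinforcement sensitivity.
name: rat-acute-crossover
task: rat
task_config:
  n_trials_per_session: 200
  n_sessions: 5
  p_good: 0.8
  reversal_criterion: 8
design: crossover
model: M2_rp_stick
groups:
  - label: vehicle
    n_subjects: 11
    means_natural: {alpha_rew: 0.25, alpha_pun: 0.45, tau_reinf: 3.0, tau_stick: 0.5}
    sds_unconstrained: {alpha_rew: 0.4, alpha_pun: 0.4, tau_reinf: 0.4, tau_stick: 0.4}
  - label: ssri-1mg
    n_subjects: 11
    means_natural: {alpha_rew: 0.40, alpha_pun: 0.45, tau_reinf: 3.0, tau_stick: 0.25}
    sds_unconstrained: {alpha_rew: 0.4, alpha_pun: 0.4, tau_reinf: 0.4, tau_stick: 0.4}
  - label: ssri-10mg
    n_subjects: 11
    means_natural: {alpha_rew: 0.15, alpha_pun: 0.45, tau_reinf: 4.2, tau_stick: 0.5}
    sds_unconstrained: {alpha_rew: 0.4, alpha_pun: 0.4, tau_reinf: 0.4, tau_stick: 0.4}
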