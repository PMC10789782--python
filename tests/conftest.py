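"""Shared fixtures: small synthetic experiments and reusable fits."""

import numpy as np
import pandas as pd
import pytest

import prlkit as pk
from prlkit.inference import to_unconstrained
from prlkit.models import ModelId


def control_means(alpha_rew=0.25, alpha_pun=0.45, tau_reinf=3.0, tau_stick=0.5):
    """Unconstrained-scale group means for the default control population."""
    return {"alpha_rew": to_unconstrained("alpha_rew", alpha_rew),
            "alpha_pun": to_unconstrained("alpha_pun", alpha_pun),
            "tau_reinf": np.log(tau_reinf),
            "tau_stick": tau_stick}


def group(label="g", n=8, model=ModelId.M2_rp_stick, sds=0.4, design="between",
          **mean_overrides):
    means = control_means(**mean_overrides)
    if model is ModelId.M3_single_stick:
        means = {"alpha_reinf": means["alpha_rew"],
                 "tau_reinf": means["tau_reinf"], "tau_stick": means["tau_stick"]}
    elif model is ModelId.M4_ewa:
        means = {"ewa_phi": 0.8, "ewa_rho": 0.0,
                 "tau_reinf": means["tau_reinf"], "tau_stick": means["tau_stick"]}
    return pk.GroupSpec(label=label, n_subjects=n, model=model, means=means,
                        sds={k: sds for k in means}, design=design)


@pytest.fixture(scope="session")
def small_m2_dataset():
    """12 control rats, 2 sessions of 200 trials, generated from M2."""
    rng = np.random.default_rng(5)
    return pk.simulate_experiment([group(n=12)], pk.RatTaskConfig(n_sessions=2),
                                  rng, seed=5)


@pytest.fixture(scope="session")
def small_m2_fit(small_m2_dataset):
    """Hierarchical M2 fit of the small dataset (shared across tests)."""
    spec = pk.HierarchicalSpec(model=ModelId.M2_rp_stick, conditions=("g",))
    settings = pk.SamplerSettings(chains=4, warmup=1500, draws=1500, seed=2)
    return pk.fit(small_m2_dataset.records, spec, settings)


@pytest.fixture()
def random_trials():
    """Factory for random (choice, outcome) sequences as trial tables."""
    def make(n_trials=50, seed=0, options=("A", "B")):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "session": 0, "trial": np.arange(n_trials),
            "choice": rng.choice(options, n_trials),
            "outcome": rng.choice([1, -1], n_trials)})
    return make
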