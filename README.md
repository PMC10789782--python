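# prlkit

Computational modelling of **probabilistic reversal learning (PRL)** — the
two-option choice task, with 80%:20% feedback contingencies that reverse,
used to study behavioral flexibility in rats and humans (e.g., under
serotonergic manipulations). The package is for researchers who want to go
beyond win-stay/lose-shift counts and ask *which latent learning process*
changed between conditions.

It provides, end to end:

- **Task simulators** for both PRL variants: the human task (80 trials, one
  fixed reversal at trial 40, stimuli "A"/"B") and the rat task (200-trial
  sessions, serial reversals after 8 consecutive correct responses,
  locations "left"/"right").
- **Four reinforcement-learning models** sharing a softmax choice rule
  `P(a) ∝ exp(τ_reinf·V(a) + τ_stick·1[a = previous choice])`:
  dual learning rates (M1); dual rates + stickiness (M2); single rate +
  stickiness (M3); experience-weighted attraction + stickiness (M4). The
  stickiness term τ_stick captures outcome-independent choice repetition
  (perseveration); values update as `V ← V + α·(outcome − V)` with
  `α = α_rew` after reward (+1) and `α = α_pun` after punishment (−1).
- **Hierarchical Bayesian fitting** per condition (group means ~ N(0,1),
  subject SDs ~ HalfNormal(1) on the unconstrained scale) with an adaptive
  Metropolis-within-Gibbs engine and a random-walk fallback, both
  deterministic given a seed; convergence gated by split-chain R̂ < 1.1.
- **Bridge-sampling model comparison**: iterative optimal-bridge estimates
  of each model's log marginal likelihood and posterior model probabilities
  under the uniform 0.25 prior.
- **Effect summaries**: posterior group mean differences (MD) with
  highest-density intervals at 75/80/85/90/95% and the flag legend
  `***`/`**`/`*`/`..`/`.`/`-` for the highest level excluding zero.
- **Validation experiments**: parameter recovery (simulate → fit → compare
  to retained truth) and posterior-predictive retrodiction of win-stay,
  lose-shift and completed reversals (default 40 simulated subjects per
  group).
- A **synthetic-data generator** with presets mirroring six experimental
  designs (8 vs 8, 11 × 3 cross-over, 7 vs 7, 32 vs 33), since no raw
  behavioral data are distributed.

## Worked example

Simulate the 8-vs-8 depletion design, fit the winning model with both
conditions in one hierarchy, and print the effects table
(`examples/04_effect_table.py`):

```python
import numpy as np
import prlkit as pk
from prlkit.models import ModelId

specs, task = pk.build_from_preset(pk.load_preset("rat-depletion"))
dataset = pk.simulate_experiment(specs, task, np.random.default_rng(3), seed=3)

hspec = pk.HierarchicalSpec(model=ModelId.M2_rp_stick,
                            conditions=("sham", "depletion"))
samples = pk.fit(dataset.records, hspec,
                 pk.SamplerSettings(chains=4, warmup=2500, draws=2500, seed=3))
for p in hspec.param_names:
    eff = pk.summarize_effect(p, pk.condition_contrast(samples, p,
                                                       "depletion", "sham"))
    print(p, round(eff.md_mean, 3), eff.flag)
```

Output:

```
max split R-hat: 1.054

parameter          MD              95% HDI  flag
alpha_rew      -0.143 [  -0.257,   -0.028]  ***
alpha_pun      -0.000 [  -0.194,    0.199]  -
tau_reinf      -0.202 [  -1.857,    1.398]  -
tau_stick      -0.350 [  -0.735,    0.032]  **
```

The generating population lowered stickiness by 0.4 and the reward learning
rate by 0.13 in the "depletion" group: the fit flags exactly those two
parameters (reward learning rate with 0 outside the 95% HDI, stickiness
outside the 90% HDI) and correctly leaves the untouched parameters
unflagged. Each `examples/` script demonstrates one capability the same
way: simulation and behavioral summaries (01), a single-group fit (02),
four-model comparison — the generating model wins with posterior
probability 0.991 (03), retrodiction at 40 simulated subjects per group
(05), and parameter recovery (06).

A thin CLI wraps the same calls
(`prlkit simulate|fit|compare|diagnose|retrodict|recover|summarize`); every
run writes a manifest (config hash, seed, version) so any output is
reproducible from its manifest alone.

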