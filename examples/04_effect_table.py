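"""Condition contrasts with HDIs and significance flags.

Simulates the depletion design (8 vs 8 rats), fits the winning model with
both conditions in one hierarchy, and prints the machine twin of a
parameter-effects table: the posterior group mean difference (MD,
depletion minus sham) with highest-density intervals, flagged by the
highest HDI level excluding zero (*** 95%, ** 90%, * 85%, .. 80%, . 75%,
- none).
"""

import numpy as np

import prlkit as pk
from prlkit.models import ModelId

specs, task = pk.build_from_preset(pk.load_preset("rat-depletion"))
dataset = pk.simulate_experiment(specs, task, np.random.default_rng(3), seed=3)

hspec = pk.HierarchicalSpec(model=ModelId.M2_rp_stick,
                            conditions=("sham", "depletion"))
samples = pk.fit(dataset.records, hspec,
                 pk.SamplerSettings(chains=4, warmup=2500, draws=2500, seed=3))
print(f"max split R-hat: {samples.max_rhat():.3f}\n")

print(f"{'parameter':12s} {'MD':>8s} {'95% HDI':>20s}  flag")
for p in hspec.param_names:
    md = pk.condition_contrast(samples, p, "depletion", "sham")
    eff = pk.summarize_effect(p, md)
    h = eff.hdis[0.95]
    print(f"{p:12s} {eff.md_mean:8.3f} [{h.lower:8.3f}, {h.upper:8.3f}]  {eff.flag}")

print("\nThe generating contrast lowered stickiness by 0.4 and the reward"
      "\nlearning rate by 0.13; flags mark which effects the 8-vs-8 design"
      "\nresolves at which credibility level.")
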