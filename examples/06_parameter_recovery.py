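"""Parameter recovery: simulate from known values, fit, compare.

Generates 20 subjects x 400 trials from the dual-rate + stickiness model,
fits it back with the retained ground truth hidden from the fitter, and
reports per-parameter Pearson correlation, bias and RMSE between the
generating values and the per-subject posterior means.
"""

import numpy as np

import prlkit as pk
from prlkit.inference import to_unconstrained
from prlkit.models import ModelId

truth = {"alpha_rew": 0.25, "alpha_pun": 0.45, "tau_reinf": 3.0,
         "tau_stick": 0.5}
means = {k: float(to_unconstrained(k, v)) for k, v in truth.items()}
spec = pk.GroupSpec(label="g", n_subjects=20, model=ModelId.M2_rp_stick,
                    means=means, sds={k: 0.4 for k in means})

report = pk.recovery_experiment(
    [spec], pk.RatTaskConfig(n_sessions=2),
    pk.SamplerSettings(chains=4, warmup=2000, draws=2000, seed=2),
    np.random.default_rng(2))

print(f"max split R-hat: {report['max_rhat']:.3f}\n")
print(f"{'parameter':12s} {'pearson r':>10s} {'bias':>8s} {'rmse':>8s}")
for p, s in report["per_parameter"].items():
    print(f"{p:12s} {s['pearson_r']:10.3f} {s['bias']:+8.3f} {s['rmse']:8.3f}")
print("\nCorrelations near 1 mean subjects' generating parameters are"
      "\nrecovered in rank and scale; hierarchical shrinkage keeps RMSE low"
      "\nat the cost of mild attenuation for weakly identified parameters.")
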