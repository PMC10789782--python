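"""Numba-compiled likelihood kernels.

These are the hot path of the hierarchical sampler: one call evaluates the
full choice-sequence log-likelihood for one subject under one model. The
pure-Python step functions in :mod:`prlkit.models` define the reference
semantics; these kernels must agree with them to machine precision (the test
suite enforces |delta| < 1e-10 against a naive re-derivation).

Model codes: 1 = reward/punishment learning rates, no stickiness;
2 = reward/punishment rates + stickiness; 3 = single rate + stickiness;
4 = experience-weighted attraction + stickiness.
"""

import numpy as np
from numba import njit

__all__ = ["loglik_kernel", "MODEL_CODES"]

MODEL_CODES = {"M1_rp": 1, "M2_rp_stick": 2, "M3_single_stick": 3, "M4_ewa": 4}


@njit(cache=True, fastmath=False)
def _log_softmax_pair(l0, l1, c):
    m = l0 if l0 > l1 else l1
    lse = m + np.log(np.exp(l0 - m) + np.exp(l1 - m))
    return (l0 if c == 0 else l1) - lse


@njit(cache=True, fastmath=False)
def loglik_kernel(choices, outcomes, model_code,
                  a_rew, a_pun, t_reinf, t_stick, phi, rho):
    """Sequence log-likelihood for one subject.

    choices: int64 array of 0/1 option indices, already ordered by
    (session, trial). outcomes: float64 array of +1/-1. Latent state starts
    at value 0 for both options, no previous choice, EWA experience weight 1.
    """
    n = choices.shape[0]
    q0 = 0.0
    q1 = 0.0
    ew = 1.0
    last = -1
    ll = 0.0
    for t in range(n):
        s0 = t_stick if last == 0 else 0.0
        s1 = t_stick if last == 1 else 0.0
        if model_code == 1:
            s0 = 0.0
            s1 = 0.0
        c = choices[t]
        ll += _log_softmax_pair(t_reinf * q0 + s0, t_reinf * q1 + s1, c)
        o = outcomes[t]
        if model_code == 4:
            ew_new = rho * ew + 1.0
            if c == 0:
                q0 = (phi * ew * q0 + o) / ew_new
                q1 = (phi * ew * q1) / ew_new
            else:
                q1 = (phi * ew * q1 + o) / ew_new
                q0 = (phi * ew * q0) / ew_new
            ew = ew_new
        else:
            a = a_rew if o > 0.0 else a_pun
            if c == 0:
                q0 += a * (o - q0)
            else:
                q1 += a * (o - q1)
        last = c
    return ll
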