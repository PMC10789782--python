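"""Hierarchical Bayesian estimation of RL model parameters.

The generative model, per experiment and candidate model, on the
*unconstrained* scale (learning rates and EWA decays are inverse-logit
transformed into (0,1), reinforcement sensitivity is log-transformed into
(0, inf), stickiness is a free real):

Between-group design (each subject belongs to exactly one condition)::

    mu[c,p]      ~ Normal(0, 1)           condition-level group mean
    sigma[c,p]   ~ HalfNormal(1)          between-subject SD
    theta[j,p]   ~ Normal(mu[c_j,p], sigma[c_j,p])
    choices_j    ~ RL model at natural(theta[j,:])

Cross-over design (every subject performs every condition)::

    mu[p]        ~ Normal(0, 1)           population baseline mean
    sigma[p]     ~ HalfNormal(1)
    delta[c,p]   ~ Normal(0, 1)           condition offset
    b[j,p]       ~ Normal(mu[p], sigma[p])  subject baseline
    choices_jc   ~ RL model at natural(b[j,:] + delta[c,:])

The condition group mean on the natural scale is ``natural(mu[c,p])``
(between) or ``natural(mu[p] + delta[c,p])`` (cross-over), and the group
mean difference (MD) between two conditions is the per-draw difference of
those natural-scale means.

Two sampling engines share the identical joint density:

* ``gibbs`` (default) — Metropolis-within-Gibbs: adaptive random-walk
  updates for subject blocks (and condition offsets), exact conjugate
  normal updates for the group means, and univariate slice sampling for the
  group SDs. The centered parameterisation keeps the mean updates conjugate.
* ``rwm`` — a generic adaptive random-walk Metropolis on the full joint
  ``joint_log_density``; dependency-light fallback used mainly for
  cross-validation.

Both engines are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._kernels import MODEL_CODES, loglik_kernel
from .models import MODEL_PARAM_NAMES, ModelId

__all__ = [
    "TRANSFORMS",
    "to_natural",
    "to_unconstrained",
    "HierarchicalSpec",
    "SamplerSettings",
    "ExperimentData",
    "prepare_experiment",
    "joint_log_density",
    "fit",
    "condition_contrast",
    "PosteriorSamples",
    "sample_rwm",
    "slice_sample_1d",
]

# ---------------------------------------------------------------------------
# parameter transforms (unconstrained -> natural)

TRANSFORMS: dict[str, str] = {
    "alpha_rew": "logistic",
    "alpha_pun": "logistic",
    "alpha_reinf": "logistic",
    "tau_reinf": "log",      # natural = exp(unconstrained)
    "tau_stick": "identity",
    "ewa_phi": "logistic",
    "ewa_rho": "logistic",
}


def to_natural(name: str, x):
    kind = TRANSFORMS[name]
    if kind == "logistic":
        return expit(x)
    if kind == "log":
        return np.exp(x)
    return x


def to_unconstrained(name: str, y):
    kind = TRANSFORMS[name]
    if kind == "logistic":
        return logit(y)
    if kind == "log":
        return np.log(y)
    return y


def _safe_exp(x: float) -> float:
    """exp with a clipped argument: wild sampler proposals far outside the
    posterior stay finite and are rejected by their likelihood instead of
    overflowing."""
    return math.exp(min(x, 50.0))


def _kernel_args_fn(model: ModelId):
    """Closure mapping an unconstrained parameter vector (canonical order)
    to the numba kernel's argument tuple."""
    code = MODEL_CODES[model.value]
    if model is ModelId.M1_rp:
        def f(u):
            return (code, expit(u[0]), expit(u[1]), _safe_exp(u[2]), 0.0, 0.5, 0.5)
    elif model is ModelId.M2_rp_stick:
        def f(u):
            return (code, expit(u[0]), expit(u[1]), _safe_exp(u[2]), u[3], 0.5, 0.5)
    elif model is ModelId.M3_single_stick:
        def f(u):
            a = expit(u[0])
            return (code, a, a, _safe_exp(u[1]), u[2], 0.5, 0.5)
    else:  # M4_ewa
        def f(u):
            return (code, 0.5, 0.5, _safe_exp(u[2]), u[3], expit(u[0]), expit(u[1]))
    return f


# ---------------------------------------------------------------------------
# specs and data views


@dataclass(frozen=True)
class HierarchicalSpec:
    """Model + design + priors of one hierarchical fit.

    ``prior_mean`` maps parameter name -> (location, scale) of the Normal
    prior on the unconstrained group mean; ``prior_sd_scale`` is the
    HalfNormal scale of the between-subject SD. Defaults are the weakly
    informative Normal(0,1) / HalfNormal(1).
    """

    model: ModelId
    conditions: tuple[str, ...]
    design: str = "between"  # "between" | "crossover"
    prior_mean: dict = field(default_factory=dict)
    prior_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.design not in ("between", "crossover"):
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAM_NAMES[ModelId(self.model)]

    def mean_prior(self, name: str) -> tuple[float, float]:
        return self.prior_mean.get(name, (0.0, 1.0))


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    engine: str = "gibbs"  # "gibbs" | "rwm"
    init_jitter: float = 0.1
    max_init_retries: int = 20


@dataclass
class ExperimentData:
    """Flat view of one experiment's trial table for the fitter.

    ``blocks`` holds one (subject index, condition index, choices, outcomes)
    tuple per subject-condition sequence, choices as 0/1 option indices
    ordered by (session, trial).
    """

    subjects: list[str]
    conditions: list[str]
    blocks: list[tuple[int, int, np.ndarray, np.ndarray]]
    option_order: list[str]
    subject_condition: np.ndarray | None  # between design only

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def prepare_experiment(df: pd.DataFrame, conditions: list[str] | None = None,
                       design: str = "between") -> ExperimentData:
    """Build the fitter's data view from a long-format trial table."""
    required = {"subject_id", "condition", "session", "trial", "choice", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")
    if conditions is None:
        conditions = sorted(df["condition"].unique())
    option_order = sorted(df["choice"].unique())
    if len(option_order) > 2:
        raise ValueError(f"expected two options, got {option_order}")
    opt_idx = {o: i for i, o in enumerate(option_order)}
    subjects = sorted(df["subject_id"].unique())
    subj_idx = {s: i for i, s in enumerate(subjects)}
    cond_idx = {c: i for i, c in enumerate(conditions)}

    blocks = []
    subj_cond = np.full(len(subjects), -1, dtype=int)
    for (sid, cond), grp in df.groupby(["subject_id", "condition"], sort=True):
        if cond not in cond_idx:
            raise ValueError(f"condition {cond!r} not in {conditions}")
        grp = grp.sort_values(["session", "trial"])
        choices = grp["choice"].map(opt_idx).to_numpy(dtype=np.int64)
        outcomes = grp["outcome"].to_numpy(dtype=np.float64)
        if not np.all(np.isin(outcomes, (1.0, -1.0))):
            raise ValueError(f"non +1/-1 outcome for subject {sid!r}")
        j, c = subj_idx[sid], cond_idx[cond]
        blocks.append((j, c, choices, outcomes))
        if design == "between":
            if subj_cond[j] not in (-1, c):
                raise ValueError(
                    f"subject {sid!r} appears in two conditions under a between design")
            subj_cond[j] = c
    if design == "between" and np.any(subj_cond < 0):
        raise ValueError("some subject has no trials")
    return ExperimentData(subjects=subjects, conditions=list(conditions),
                          blocks=blocks, option_order=option_order,
                          subject_condition=subj_cond if design == "between" else None)


# ---------------------------------------------------------------------------
# latent vector layout


class _Layout:
    """Index bookkeeping for the flat unconstrained latent vector."""

    def __init__(self, spec: HierarchicalSpec, data: ExperimentData):
        self.spec = spec
        P = len(spec.param_names)
        C = len(data.conditions)
        S = data.n_subjects
        self.P, self.C, self.S = P, C, S
        names: list[str] = []
        if spec.design == "between":
            for c in data.conditions:
                names += [f"mu[{c},{p}]" for p in spec.param_names]
            for c in data.conditions:
                names += [f"log_sigma[{c},{p}]" for p in spec.param_names]
            self.mu_off, self.ls_off, self.theta_off = 0, C * P, 2 * C * P
        else:
            # reference coding: the first condition's offset is fixed at 0,
            # which identifies the baseline/offset decomposition
            names += [f"mu[{p}]" for p in spec.param_names]
            names += [f"log_sigma[{p}]" for p in spec.param_names]
            for c in data.conditions[1:]:
                names += [f"delta[{c},{p}]" for p in spec.param_names]
            self.mu_off, self.ls_off = 0, P
            self.delta_off = 2 * P
            self.theta_off = 2 * P + (C - 1) * P
        for s in data.subjects:
            names += [f"theta[{s},{p}]" for p in spec.param_names]
        self.names = names
        self.K = len(names)

    # views into a flat vector ------------------------------------------------
    def mu(self, z):
        shape = (self.C, self.P) if self.spec.design == "between" else (self.P,)
        return z[self.mu_off:self.mu_off + int(np.prod(shape))].reshape(shape)

    def log_sigma(self, z):
        shape = (self.C, self.P) if self.spec.design == "between" else (self.P,)
        return z[self.ls_off:self.ls_off + int(np.prod(shape))].reshape(shape)

    def delta(self, z):
        """(C, P) condition offsets; row 0 (reference condition) is zero."""
        free = z[self.delta_off:self.delta_off + (self.C - 1) * self.P]
        return np.concatenate([np.zeros((1, self.P)), free.reshape(self.C - 1, self.P)])

    def theta(self, z):
        return z[self.theta_off:self.theta_off + self.S * self.P].reshape(self.S, self.P)


_LOG_HALF_NORMAL_CONST = 0.5 * math.log(2.0 / math.pi)


def _log_normal(x, loc, scale):
    return -0.5 * math.log(2 * math.pi) - np.log(scale) - 0.5 * ((x - loc) / scale) ** 2


def _log_half_normal_from_ls(ls, scale):
    """log HalfNormal(sigma | scale) + log |d sigma / d log sigma| at sigma=exp(ls)."""
    sigma = np.exp(ls)
    return _LOG_HALF_NORMAL_CONST - math.log(scale) - 0.5 * (sigma / scale) ** 2 + ls


def joint_log_density(data: ExperimentData, spec: HierarchicalSpec,
                      z: np.ndarray) -> float:
    """Log joint density of the hierarchical model at a flat latent vector.

    Sum of group-level log-priors, subject-deviation log-densities and the
    per-subject RL sequence log-likelihoods at the transformed natural
    parameters, including the log-Jacobian of the ``sigma = exp(log_sigma)``
    reparameterisation. Finite for finite input.
    """
    z = np.asarray(z, dtype=float)
    if np.any(np.isnan(z)):
        raise ValueError("NaN in latent vector")
    lay = _Layout(spec, data)
    if z.shape != (lay.K,):
        raise ValueError(f"latent vector has length {z.shape}, expected ({lay.K},)")
    mu, ls, theta = lay.mu(z), lay.log_sigma(z), lay.theta(z)
    sigma = np.exp(ls)
    lp = 0.0
    for i, p in enumerate(spec.param_names):
        loc, scale = spec.mean_prior(p)
        lp += float(np.sum(_log_normal(np.atleast_1d(mu)[..., i], loc, scale)))
        lp += float(np.sum(_log_half_normal_from_ls(
            np.atleast_1d(ls)[..., i], spec.prior_sd_scale)))
    if spec.design == "between":
        sc = data.subject_condition
        lp += float(np.sum(_log_normal(theta, mu[sc], sigma[sc])))
    else:
        delta = lay.delta(z)
        lp += float(np.sum(_log_normal(delta[1:], 0.0, 1.0)))  # reference row fixed
        lp += float(np.sum(_log_normal(theta, mu, sigma)))
    kargs = _kernel_args_fn(ModelId(spec.model))
    for j, c, choices, outcomes in data.blocks:
        u = theta[j] if spec.design == "between" else theta[j] + lay.delta(z)[c]
        lp += loglik_kernel(choices, outcomes, *kargs(u))
    return float(lp)


# ---------------------------------------------------------------------------
# generic 1-D slice sampler and adaptive RWM


def slice_sample_1d(logf, x0: float, rng: np.random.Generator,
                    w: float = 1.0, max_steps: int = 50) -> float:
    """Univariate slice sampling with stepping-out (Neal 2003)."""
    y = logf(x0) + math.log(rng.random())
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    j = int(rng.integers(max_steps))
    k = max_steps - 1 - j
    while j > 0 and logf(lo) > y:
        lo -= w
        j -= 1
    while k > 0 and logf(hi) > y:
        hi += w
        k -= 1
    for _ in range(200):
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological shrinkage; keep current point


def sample_rwm(logpdf, x0: np.ndarray, *, warmup: int, draws: int,
               rng: np.random.Generator, scale0: float = 0.1,
               target_accept: float = 0.3) -> np.ndarray:
    """Adaptive random-walk Metropolis; returns post-warmup draws (draws, K).

    The proposal is an isotropic normal whose scale adapts toward the target
    acceptance rate during warmup (Robbins-Monro on the log scale) and is
    frozen afterwards.
    """
    x = np.array(x0, dtype=float)
    K = x.size
    lp = logpdf(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite density at the initial point")
    log_scale = math.log(scale0)
    out = np.empty((draws, K))
    for it in range(warmup + draws):
        prop = x + math.exp(log_scale) * rng.standard_normal(K)
        lp_prop = logpdf(prop)
        acc = min(1.0, math.exp(min(0.0, lp_prop - lp))) if np.isfinite(lp_prop) else 0.0
        if rng.random() < acc:
            x, lp = prop, lp_prop
        if it < warmup:
            log_scale += (acc - target_accept) / (1.0 + it) ** 0.6
        else:
            out[it - warmup] = x
    return out


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """MCMC draws of the full unconstrained latent vector.

    ``z`` has shape (chains, draws, K); ``names`` labels the K latents
    ("mu[...]", "log_sigma[...]", "delta[...]", "theta[...]").
    """

    z: np.ndarray
    names: list[str]
    spec: HierarchicalSpec
    subjects: list[str]
    conditions: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.z.ndim != 3 or self.z.shape[0] < 2:
            raise ValueError("need >= 2 chains of draws")
        self._idx = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.z.shape[0]

    @property
    def n_draws(self) -> int:
        return self.z.shape[1]

    def latent(self, name: str) -> np.ndarray:
        """(chains, draws) array of one named latent."""
        return self.z[:, :, self._idx[name]]

    def group_mean_unconstrained(self, param: str, condition: str) -> np.ndarray:
        if self.spec.design == "between":
            return self.latent(f"mu[{condition},{param}]")
        mu = self.latent(f"mu[{param}]")
        if condition == self.conditions[0]:  # reference: offset fixed at 0
            return mu
        return mu + self.latent(f"delta[{condition},{param}]")

    def group_mean_natural(self, param: str, condition: str) -> np.ndarray:
        return to_natural(param, self.group_mean_unconstrained(param, condition))

    def subject_unconstrained(self, param: str, subject: str,
                              condition: str | None = None) -> np.ndarray:
        th = self.latent(f"theta[{subject},{param}]")
        if self.spec.design == "crossover":
            if condition is None:
                raise ValueError("crossover design needs a condition")
            if condition != self.conditions[0]:
                th = th + self.latent(f"delta[{condition},{param}]")
        return th

    def subject_natural(self, param: str, subject: str,
                        condition: str | None = None) -> np.ndarray:
        return to_natural(param, self.subject_unconstrained(param, subject, condition))

    def flat(self) -> np.ndarray:
        """(chains*draws, K) matrix of unconstrained draws (chain-major)."""
        return self.z.reshape(-1, self.z.shape[2])

    def max_rhat(self) -> float:
        from .diagnostics import rhat
        vals = []
        for k in range(self.z.shape[2]):
            col = self.z[:, :, k]
            if np.ptp(col) == 0:
                continue
            vals.append(rhat(col))
        return max(vals) if vals else 1.0

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format draws table (chain, draw, parameter, value)."""
        C, D, K = self.z.shape
        chain = np.repeat(np.arange(C), D * K)
        draw = np.tile(np.repeat(np.arange(D), K), C)
        param = np.tile(np.array(self.names, dtype=object), C * D)
        return pd.DataFrame({"chain": chain, "draw": draw, "parameter": param,
                             "value": self.z.reshape(-1)})

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, spec: HierarchicalSpec,
                        subjects: list[str], conditions: list[str],
                        metadata: dict | None = None) -> "PosteriorSamples":
        names = list(df[df["chain"] == 0][df["draw"] == 0]["parameter"]) \
            if False else list(pd.unique(df["parameter"]))
        C = int(df["chain"].max()) + 1
        D = int(df["draw"].max()) + 1
        piv = df.pivot_table(index=["chain", "draw"], columns="parameter",
                             values="value", sort=False)
        z = piv[names].to_numpy().reshape(C, D, len(names))
        return cls(z=z, names=names, spec=spec, subjects=subjects,
                   conditions=conditions, metadata=metadata or {})


def condition_contrast(samples: PosteriorSamples, param: str,
                       cond_a: str, cond_b: str) -> np.ndarray:
    """Posterior draws of the group mean difference MD = A - B on the
    natural scale, draw-aligned; returned pooled over chains."""
    for c in (cond_a, cond_b):
        if c not in samples.conditions:
            raise KeyError(f"condition {c!r} was not fitted")
    md = (samples.group_mean_natural(param, cond_a)
          - samples.group_mean_natural(param, cond_b))
    return md.reshape(-1)


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs engine


def _conjugate_normal_mean(values: np.ndarray, sigma: float,
                           prior_loc: float, prior_scale: float,
                           rng: np.random.Generator) -> float:
    n = values.size
    prec = 1.0 / prior_scale ** 2 + n / sigma ** 2
    mean = (prior_loc / prior_scale ** 2 + values.sum() / sigma ** 2) / prec
    return mean + rng.standard_normal() / math.sqrt(prec)


def _gibbs_chain(data: ExperimentData, spec: HierarchicalSpec, lay: _Layout,
                 settings: SamplerSettings, rng: np.random.Generator) -> np.ndarray:
    P, C, S = lay.P, lay.C, lay.S
    kargs = _kernel_args_fn(ModelId(spec.model))
    between = spec.design == "between"
    prior_loc = np.array([spec.mean_prior(p)[0] for p in spec.param_names])
    prior_scale = np.array([spec.mean_prior(p)[1] for p in spec.param_names])
    sd_scale = spec.prior_sd_scale

    # subject -> list of blocks
    subj_blocks: list[list[tuple[int, np.ndarray, np.ndarray]]] = [[] for _ in range(S)]
    cond_blocks: list[list[tuple[int, np.ndarray, np.ndarray]]] = [[] for _ in range(C)]
    for j, c, ch, oc in data.blocks:
        subj_blocks[j].append((c, ch, oc))
        cond_blocks[c].append((j, ch, oc))

    def subj_loglik(j: int, th_j: np.ndarray, delta: np.ndarray | None) -> float:
        ll = 0.0
        for c, ch, oc in subj_blocks[j]:
            u = th_j if between else th_j + delta[c]
            ll += loglik_kernel(ch, oc, *kargs(u))
        return ll

    # --- initialisation (jittered around the prior mean) ---
    mu = (np.tile(prior_loc, (C, 1)) if between else prior_loc.copy())
    mu = mu + settings.init_jitter * rng.standard_normal(mu.shape)
    ls = math.log(0.5) + settings.init_jitter * rng.standard_normal(mu.shape)
    delta = None
    if not between:
        delta = settings.init_jitter * rng.standard_normal((C, P))
        delta[0] = 0.0  # reference condition
    theta = np.empty((S, P))
    for j in range(S):
        base = mu[data.subject_condition[j]] if between else mu
        theta[j] = base + settings.init_jitter * rng.standard_normal(P)
    for attempt in range(settings.max_init_retries + 1):
        ok = all(np.isfinite(subj_loglik(j, theta[j], delta)) for j in range(S))
        if ok:
            break
        if attempt == settings.max_init_retries:
            raise RuntimeError("non-finite density at initialization after retries")
        theta += settings.init_jitter * rng.standard_normal(theta.shape)

    subj_log_scale = np.full(S, math.log(0.2))
    delta_log_scale = np.full(C, math.log(0.1))
    asis_log_scale = np.full((C if between else 1, P), math.log(0.3))
    subj_ll = np.array([subj_loglik(j, theta[j], delta) for j in range(S)])

    # per-subject adaptive-covariance proposals (Haario-style): Welford
    # accumulators feed a Cholesky factor recomputed periodically in warmup
    subj_chol = np.tile(np.eye(P), (S, 1, 1))
    acc_mean = theta.copy()
    acc_m2 = np.zeros((S, P, P))
    acc_n = 0
    base = 2.38 / math.sqrt(P)

    out = np.empty((settings.draws, lay.K))
    total = settings.warmup + settings.draws
    for it in range(total):
        adapt = it < settings.warmup
        kappa = 1.0 / (1.0 + it) ** 0.6

        # -- subject blocks (random-walk MH) --
        for j in range(S):
            m = mu[data.subject_condition[j]] if between else mu
            s = np.exp(ls[data.subject_condition[j]] if between else ls)
            step = subj_chol[j] @ rng.standard_normal(P)
            prop = theta[j] + math.exp(subj_log_scale[j]) * step
            ll_prop = subj_loglik(j, prop, delta)
            lp_cur = subj_ll[j] + float(np.sum(_log_normal(theta[j], m, s)))
            lp_prop = ll_prop + float(np.sum(_log_normal(prop, m, s)))
            a = math.exp(min(0.0, lp_prop - lp_cur)) if np.isfinite(lp_prop) else 0.0
            if rng.random() < a:
                theta[j] = prop
                subj_ll[j] = ll_prop
            if adapt:
                subj_log_scale[j] += kappa * (a - 0.3)

        if adapt:
            # windowed adaptation: drop the early, unconverged history so the
            # proposal covariance reflects the stationary region
            if it in (settings.warmup // 4, settings.warmup // 2):
                acc_n = 0
                acc_mean = theta.copy()
                acc_m2[:] = 0.0
            acc_n += 1
            d1 = theta - acc_mean
            acc_mean += d1 / acc_n
            acc_m2 += np.einsum("jp,jq->jpq", d1, theta - acc_mean)
            if acc_n >= 50 and it % 25 == 24:
                cov = acc_m2 / acc_n + 1e-8 * np.eye(P)
                # floor the diagonal so a temporarily stuck block cannot
                # freeze its own proposal permanently
                di = np.arange(P)
                cov[:, di, di] = np.maximum(cov[:, di, di], 1e-4)
                first_switch = not np.any(subj_chol != np.eye(P))
                for j in range(S):
                    try:
                        subj_chol[j] = base * np.linalg.cholesky(cov[j])
                    except np.linalg.LinAlgError:
                        pass
                if first_switch:
                    subj_log_scale[:] = 0.0

        # -- condition offsets (crossover only) --
        if not between:
            for c in range(1, C):
                prop_d = delta[c] + math.exp(delta_log_scale[c]) * rng.standard_normal(P)
                ll_cur = ll_prop_tot = 0.0
                for j, ch, oc in cond_blocks[c]:
                    ll_cur += loglik_kernel(ch, oc, *kargs(theta[j] + delta[c]))
                    ll_prop_tot += loglik_kernel(ch, oc, *kargs(theta[j] + prop_d))
                lp_cur = ll_cur + float(np.sum(_log_normal(delta[c], 0.0, 1.0)))
                lp_prop = ll_prop_tot + float(np.sum(_log_normal(prop_d, 0.0, 1.0)))
                a = math.exp(min(0.0, lp_prop - lp_cur)) if np.isfinite(lp_prop) else 0.0
                if rng.random() < a:
                    delta[c] = prop_d
                if adapt:
                    delta_log_scale[c] += kappa * (a - 0.3)
            # subject logliks depend on delta; refresh cache
            subj_ll = np.array([subj_loglik(j, theta[j], delta) for j in range(S)])

        # -- ASIS interweave: non-centered scale move. Holding the
        # standardized subject deviations eta fixed, a log-sigma proposal
        # rescales the whole subject cloud about its mean, which lets the
        # sampler climb out of the funnel where a collapsed sigma pins every
        # subject to the group mean. Conditional on eta the N(theta|mu,sigma)
        # terms reduce to N(eta|0,1), constant in log-sigma, so the target is
        # the half-normal prior (with Jacobian) plus the data likelihood. --
        group_members = ([np.flatnonzero(data.subject_condition == c)
                          for c in range(C)] if between
                         else [np.arange(S)])
        for gi, members in enumerate(group_members):
            if members.size == 0:
                continue
            mu_g = mu[gi] if between else mu
            ls_g = ls[gi] if between else ls
            for p in range(P):
                sig_cur = math.exp(ls_g[p])
                eta = (theta[members, p] - mu_g[p]) / sig_cur
                prop_ls = ls_g[p] + math.exp(asis_log_scale[gi, p]) * \
                    rng.standard_normal()
                new_col = mu_g[p] + math.exp(prop_ls) * eta
                theta_try = theta[members].copy()
                theta_try[:, p] = new_col
                ll_members = np.array([subj_loglik(j, theta_try[row], delta)
                                       for row, j in enumerate(members)])
                lp_cur = (subj_ll[members].sum()
                          + _log_half_normal_from_ls(ls_g[p], sd_scale))
                lp_prop = (ll_members.sum()
                           + _log_half_normal_from_ls(prop_ls, sd_scale))
                a = math.exp(min(0.0, lp_prop - lp_cur)) if np.isfinite(lp_prop) \
                    else 0.0
                if rng.random() < a:
                    ls_g[p] = prop_ls
                    theta[members, p] = new_col
                    subj_ll[members] = ll_members
                if adapt:
                    asis_log_scale[gi, p] += kappa * (a - 0.3)

        # -- group means (conjugate) and SDs (slice) --
        if between:
            for c in range(C):
                members = theta[data.subject_condition == c]
                for p in range(P):
                    sig = math.exp(ls[c, p])
                    mu[c, p] = _conjugate_normal_mean(
                        members[:, p], sig, prior_loc[p], prior_scale[p], rng)
                    ss = float(np.sum((members[:, p] - mu[c, p]) ** 2))
                    n = members.shape[0]

                    def logf(x, ss=ss, n=n):
                        return (-n * x - ss / (2.0 * math.exp(2.0 * x))
                                + _log_half_normal_from_ls(x, sd_scale))

                    ls[c, p] = slice_sample_1d(logf, ls[c, p], rng)
        else:
            for p in range(P):
                sig = math.exp(ls[p])
                mu[p] = _conjugate_normal_mean(
                    theta[:, p], sig, prior_loc[p], prior_scale[p], rng)
                ss = float(np.sum((theta[:, p] - mu[p]) ** 2))

                def logf(x, ss=ss, n=S):
                    return (-n * x - ss / (2.0 * math.exp(2.0 * x))
                            + _log_half_normal_from_ls(x, sd_scale))

                ls[p] = slice_sample_1d(logf, ls[p], rng)

        if not adapt:
            d = it - settings.warmup
            vec = out[d]
            vec[lay.mu_off:lay.mu_off + mu.size] = mu.ravel()
            vec[lay.ls_off:lay.ls_off + ls.size] = ls.ravel()
            if not between:
                vec[lay.delta_off:lay.delta_off + (C - 1) * P] = delta[1:].ravel()
            vec[lay.theta_off:] = theta.ravel()
    return out


def fit(df: pd.DataFrame, spec: HierarchicalSpec,
        settings: SamplerSettings | None = None,
        data: ExperimentData | None = None) -> PosteriorSamples:
    """Fit the hierarchical model to a long-format trial table.

    Returns :class:`PosteriorSamples` with split-R-hat computable from the
    stored chains. Deterministic given ``settings.seed`` and engine.
    """
    settings = settings or SamplerSettings()
    if data is None:
        data = prepare_experiment(df, conditions=list(spec.conditions),
                                  design=spec.design)
    if data.n_subjects < 1:
        raise ValueError("need at least one subject")
    if spec.design == "between":
        present = set(data.subject_condition.tolist())
        if present != set(range(len(data.conditions))):
            raise ValueError("every condition needs at least one subject")
    lay = _Layout(spec, data)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    chains = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        if settings.engine == "gibbs":
            chains.append(_gibbs_chain(data, spec, lay, settings, rng))
        elif settings.engine == "rwm":
            x0 = np.zeros(lay.K)
            x0[lay.ls_off:lay.ls_off + (lay.C * lay.P if spec.design == "between"
                                        else lay.P)] = math.log(0.5)
            x0 += settings.init_jitter * rng.standard_normal(lay.K)
            chains.append(sample_rwm(lambda z: joint_log_density(data, spec, z),
                                     x0, warmup=settings.warmup,
                                     draws=settings.draws, rng=rng))
        else:
            raise ValueError(f"unknown engine {settings.engine!r}")
    z = np.stack(chains)
    meta = {"seed": settings.seed, "warmup": settings.warmup,
            "engine": settings.engine, "divergences": 0}
    return PosteriorSamples(z=z, names=lay.names, spec=spec,
                            subjects=data.subjects, conditions=data.conditions,
                            metadata=meta)
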