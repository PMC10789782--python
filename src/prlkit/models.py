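"""Reinforcement-learning models of two-choice probabilistic reversal learning.

Four candidate models, all sharing a softmax choice rule over two options:

* ``M1_rp`` — Rescorla-Wagner value learning with separate reward and
  punishment learning rates (``alpha_rew``, ``alpha_pun``) and reinforcement
  sensitivity ``tau_reinf`` (inverse temperature).
* ``M2_rp_stick`` — M1 plus a stickiness parameter ``tau_stick``: an additive
  bonus on the logit of whichever option was chosen on the previous trial,
  irrespective of its outcome. For human data the indicator tracks the
  stimulus identity; for rat data, the response location.
* ``M3_single_stick`` — as M2 but with a single learning rate ``alpha_reinf``
  applied after both reward and punishment.
* ``M4_ewa`` — experience-weighted attraction: option attractions are
  decaying payoff averages weighted by an accumulating, decaying experience
  count (payoff decay ``ewa_phi``, experience decay ``ewa_rho``), combined
  with the same sensitivity and stickiness terms in the choice rule.

Outcomes are coded +1 (reward) / -1 (punishment) and are the targets of the
value updates, so ``tau_reinf`` is the single scaling of value differences.
Values and attractions start at 0, the EWA experience weight at 1, and there
is no previous choice on the first trial (stickiness contributes nothing).

``sequence_loglik`` is the exact per-trial log-likelihood a model assigns to
an observed choice sequence; it dispatches to a numba kernel and must agree
with a naive re-derivation from the step functions below to ~1e-10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from ._kernels import MODEL_CODES, loglik_kernel

__all__ = [
    "ModelId",
    "AgentParams",
    "LatentState",
    "MODEL_PARAM_NAMES",
    "choice_logits",
    "choice_probs",
    "update_values_rp",
    "update_values_ewa",
    "update_state",
    "sequence_loglik",
    "sequence_loglik_naive",
]


class ModelId(str, Enum):
    """The closed set of four candidate models."""

    M1_rp = "M1_rp"
    M2_rp_stick = "M2_rp_stick"
    M3_single_stick = "M3_single_stick"
    M4_ewa = "M4_ewa"


#: Free parameters of each model, in canonical order.
MODEL_PARAM_NAMES: dict[ModelId, tuple[str, ...]] = {
    ModelId.M1_rp: ("alpha_rew", "alpha_pun", "tau_reinf"),
    ModelId.M2_rp_stick: ("alpha_rew", "alpha_pun", "tau_reinf", "tau_stick"),
    ModelId.M3_single_stick: ("alpha_reinf", "tau_reinf", "tau_stick"),
    ModelId.M4_ewa: ("ewa_phi", "ewa_rho", "tau_reinf", "tau_stick"),
}


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one agent under a specified model.

    Only the fields relevant to ``model`` are read. ``tau_stick`` may be
    negative (an anti-perseverative tendency).
    """

    model: ModelId
    alpha_rew: float = 0.5
    alpha_pun: float = 0.5
    alpha_reinf: float = 0.5
    tau_reinf: float = 1.0
    tau_stick: float = 0.0
    ewa_phi: float = 0.5
    ewa_rho: float = 0.5

    def __post_init__(self) -> None:
        names = MODEL_PARAM_NAMES[ModelId(self.model)]
        for nm in names:
            v = getattr(self, nm)
            if nm.startswith("alpha") or nm.startswith("ewa"):
                if not 0.0 < v < 1.0:
                    raise ValueError(f"{nm}={v} must lie in (0, 1)")
            elif nm == "tau_reinf":
                if v < 0.0:
                    raise ValueError(f"tau_reinf={v} must be >= 0")

    def to_dict(self) -> dict[str, float]:
        return {nm: getattr(self, nm) for nm in MODEL_PARAM_NAMES[ModelId(self.model)]}

    @property
    def kernel_args(self) -> tuple:
        """(model_code, a_rew, a_pun, t_reinf, t_stick, phi, rho) for the numba kernel."""
        m = ModelId(self.model)
        code = MODEL_CODES[m.value]
        if m is ModelId.M3_single_stick:
            a_rew = a_pun = self.alpha_reinf
        else:
            a_rew, a_pun = self.alpha_rew, self.alpha_pun
        t_stick = 0.0 if m is ModelId.M1_rp else self.tau_stick
        return (code, a_rew, a_pun, self.tau_reinf, t_stick,
                self.ewa_phi, self.ewa_rho)


@dataclass(frozen=True)
class LatentState:
    """Evolving latent state of one modelled sequence.

    ``values`` are Q-values (M1-M3) or EWA attractions (M4) per option index;
    ``ewa_n`` is the EWA experience weight (ignored by M1-M3).
    """

    values: tuple[float, float] = (0.0, 0.0)
    last_choice: int | None = None
    ewa_n: float = 1.0


def choice_logits(state: LatentState, params: AgentParams) -> np.ndarray:
    """Per-option logits: ``tau_reinf * value + tau_stick * 1[repeat]``.

    The stickiness term is absent for M1 and contributes nothing on the
    first trial of a sequence (no previous choice).
    """
    _, _, _, t_reinf, t_stick, _, _ = params.kernel_args
    logits = t_reinf * np.asarray(state.values, dtype=float)
    if state.last_choice is not None:
        logits[state.last_choice] += t_stick
    return logits


def choice_probs(state: LatentState, params: AgentParams) -> np.ndarray:
    """Softmax choice probabilities (normalised exponentials of the logits)."""
    logits = choice_logits(state, params)
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def _check_outcome(outcome: float) -> None:
    if outcome not in (1, -1, 1.0, -1.0):
        raise ValueError(f"outcome must be +1 or -1, got {outcome!r}")


def update_values_rp(state: LatentState, choice: int, outcome: float,
                     params: AgentParams) -> LatentState:
    """Rescorla-Wagner update for M1-M3: value += alpha * (outcome - value).

    alpha is ``alpha_rew`` after reward, ``alpha_pun`` after punishment
    (``alpha_reinf`` for both under M3). The unchosen option is untouched.
    """
    _check_outcome(outcome)
    m = ModelId(params.model)
    if m is ModelId.M4_ewa:
        raise ValueError("update_values_rp does not apply to M4_ewa")
    if m is ModelId.M3_single_stick:
        alpha = params.alpha_reinf
    else:
        alpha = params.alpha_rew if outcome > 0 else params.alpha_pun
    values = list(state.values)
    values[choice] += alpha * (outcome - values[choice])
    return replace(state, values=tuple(values), last_choice=choice)


def update_values_ewa(state: LatentState, choice: int, outcome: float,
                      params: AgentParams) -> LatentState:
    """Experience-weighted attraction update for M4.

    n' = rho * n + 1; the chosen attraction becomes a decayed average
    receiving the payoff, the unchosen attraction decays without payoff:
    V'(c) = (phi * n * V(c) + outcome) / n';  V'(u) = phi * n * V(u) / n'.
    """
    _check_outcome(outcome)
    if ModelId(params.model) is not ModelId.M4_ewa:
        raise ValueError("update_values_ewa applies only to M4_ewa")
    n_new = params.ewa_rho * state.ewa_n + 1.0
    values = list(state.values)
    for opt in (0, 1):
        num = params.ewa_phi * state.ewa_n * values[opt]
        if opt == choice:
            num += outcome
        values[opt] = num / n_new
    return LatentState(values=tuple(values), last_choice=choice, ewa_n=n_new)


def update_state(state: LatentState, choice: int, outcome: float,
                 params: AgentParams) -> LatentState:
    """Dispatch to the model's value update."""
    if ModelId(params.model) is ModelId.M4_ewa:
        return update_values_ewa(state, choice, outcome, params)
    return update_values_rp(state, choice, outcome, params)


def _extract_arrays(trials: pd.DataFrame, option_order: list | None = None):
    """Map a sorted subject-condition trial table to (choices, outcomes) arrays."""
    if not isinstance(trials, pd.DataFrame):
        trials = pd.DataFrame(trials)
    key = trials[["session", "trial"]].to_numpy()
    if len(key) > 1:
        order = np.lexsort((key[:, 1], key[:, 0]))
        if not np.array_equal(order, np.arange(len(key))):
            raise ValueError("trials must be sorted by (session, trial)")
        same_session = key[1:, 0] == key[:-1, 0]
        if np.any(same_session & (key[1:, 1] <= key[:-1, 1])):
            raise ValueError("trial indices must be strictly increasing within a session")
    if option_order is None:
        option_order = sorted(pd.unique(trials["choice"]))
    idx = {opt: i for i, opt in enumerate(option_order)}
    if len(idx) > 2:
        raise ValueError(f"expected at most 2 options, got {option_order}")
    choices = trials["choice"].map(idx)
    if choices.isna().any():
        raise ValueError("choice token outside the task option set")
    outcomes = trials["outcome"].to_numpy(dtype=np.float64)
    if not np.all(np.isin(outcomes, (1.0, -1.0))):
        raise ValueError("outcome must be +1 or -1 on every record")
    return choices.to_numpy(dtype=np.int64), outcomes


def sequence_loglik(trials: pd.DataFrame, params: AgentParams,
                    option_order: list | None = None) -> float:
    """Log-likelihood of one subject-condition choice sequence under ``params``.

    ``trials`` must be sorted by (session, trial); latent state carries
    across session boundaries within the sequence (state is NOT reset
    between sessions of the same condition).
    """
    choices, outcomes = _extract_arrays(trials, option_order)
    return float(loglik_kernel(choices, outcomes, *params.kernel_args))


def sequence_loglik_naive(trials: pd.DataFrame, params: AgentParams,
                          option_order: list | None = None) -> float:
    """Reference log-likelihood built from the step functions, one trial at a time.

    Kept deliberately independent of the numba kernel: state is re-derived
    through ``choice_probs``/``update_state`` so the two paths can be checked
    against each other.
    """
    choices, outcomes = _extract_arrays(trials, option_order)
    state = LatentState()
    ll = 0.0
    for c, o in zip(choices, outcomes):
        ll += math.log(choice_probs(state, params)[c])
        state = update_state(state, int(c), float(o), params)
    return ll
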