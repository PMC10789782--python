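"""Probabilistic reversal learning (PRL) task simulators.

Two variants of the two-option PRL task:

* **Human variant** — 80 trials with visual stimuli "A"/"B". One stimulus
  yields positive feedback on 80% of trials (the other on 20%); the
  contingencies reverse exactly once, at the fixed midpoint (trial 40,
  0-based: trials 0..39 are pre-reversal).
* **Rat variant** — sessions of 200 trials at the "left"/"right" apertures,
  same 80%:20% contingencies. A reversal is triggered whenever the animal
  makes eight consecutive correct responses; the counter counts correct
  CHOICES (not rewarded trials, which would make the criterion depend on
  feedback noise), resets on an incorrect choice and on each reversal, and
  resets at session boundaries.

Feedback is +1 (reward) with probability ``p_good`` when the currently
correct option is chosen, and with probability ``1 - p_good`` otherwise;
-1 (punishment) complements. Given the same seed and the same choice
stream, the outcome stream is bit-identical. Omissions, reaction times and
session clocks are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "HumanTaskConfig",
    "RatTaskConfig",
    "HumanTaskState",
    "RatTaskState",
    "TaskExhaustedError",
    "step_human_task",
    "step_rat_task",
    "play_task",
    "HUMAN_OPTIONS",
    "RAT_OPTIONS",
]

HUMAN_OPTIONS = ("A", "B")
RAT_OPTIONS = ("left", "right")


class TaskExhaustedError(RuntimeError):
    """Raised when stepping a task past its trial budget."""


@dataclass(frozen=True)
class HumanTaskConfig:
    """Human PRL task: one fixed-midpoint reversal."""

    n_trials: int = 80
    p_good: float = 0.8
    reversal_trial: int = 40  # first trial index with reversed contingencies

    def __post_init__(self) -> None:
        if not 0.5 < self.p_good <= 1.0:
            raise ValueError("p_good must satisfy 0.5 < p_good <= 1")
        if not 0 < self.reversal_trial < self.n_trials:
            raise ValueError("reversal_trial must lie strictly inside the task")

    options = HUMAN_OPTIONS


@dataclass(frozen=True)
class RatTaskConfig:
    """Rat PRL task: serial reversals after 8 consecutive correct choices."""

    n_trials_per_session: int = 200
    n_sessions: int = 1
    p_good: float = 0.8
    reversal_criterion: int = 8

    def __post_init__(self) -> None:
        if self.reversal_criterion < 1:
            raise ValueError("reversal_criterion must be >= 1")
        if self.n_trials_per_session < self.reversal_criterion:
            raise ValueError("session shorter than the reversal criterion")
        if not 0.5 < self.p_good <= 1.0:
            raise ValueError("p_good must satisfy 0.5 < p_good <= 1")

    options = RAT_OPTIONS


@dataclass(frozen=True)
class HumanTaskState:
    config: HumanTaskConfig
    trial: int = 0
    correct_option: str = "A"


@dataclass(frozen=True)
class RatTaskState:
    config: RatTaskConfig
    trial: int = 0  # within-session trial index
    correct_option: str = "left"
    consecutive_correct: int = 0
    reversal_count: int = 0


def _draw_outcome(chose_correct: bool, p_good: float, rng: np.random.Generator) -> int:
    p_reward = p_good if chose_correct else 1.0 - p_good
    return 1 if rng.random() < p_reward else -1


def step_human_task(state: HumanTaskState, choice: str,
                    rng: np.random.Generator) -> tuple[int, HumanTaskState]:
    """One trial of the human task; returns (outcome, new state).

    The correct option flips exactly when the trial counter crosses
    ``reversal_trial``.
    """
    cfg = state.config
    if state.trial >= cfg.n_trials:
        raise TaskExhaustedError(f"task has only {cfg.n_trials} trials")
    if choice not in HUMAN_OPTIONS:
        raise ValueError(f"unknown option {choice!r}; expected one of {HUMAN_OPTIONS}")
    outcome = _draw_outcome(choice == state.correct_option, cfg.p_good, rng)
    nxt = state.trial + 1
    correct = state.correct_option
    if nxt == cfg.reversal_trial:
        correct = HUMAN_OPTIONS[1 - HUMAN_OPTIONS.index(correct)]
    return outcome, replace(state, trial=nxt, correct_option=correct)


def step_rat_task(state: RatTaskState, choice: str,
                  rng: np.random.Generator) -> tuple[int, RatTaskState]:
    """One trial of the rat task; returns (outcome, new state).

    The consecutive-correct counter increments on a correct choice and resets
    on an incorrect one; on reaching the criterion the locations swap, the
    reversal count increments and the counter resets to 0. The reversal count
    is a deterministic function of the choice stream (feedback noise never
    enters the criterion).
    """
    cfg = state.config
    if state.trial >= cfg.n_trials_per_session:
        raise TaskExhaustedError("session trial budget exhausted")
    if choice not in RAT_OPTIONS:
        raise ValueError(f"unknown option {choice!r}; expected one of {RAT_OPTIONS}")
    chose_correct = choice == state.correct_option
    outcome = _draw_outcome(chose_correct, cfg.p_good, rng)
    streak = state.consecutive_correct + 1 if chose_correct else 0
    correct = state.correct_option
    reversals = state.reversal_count
    if streak >= cfg.reversal_criterion:
        correct = RAT_OPTIONS[1 - RAT_OPTIONS.index(correct)]
        reversals += 1
        streak = 0
    return outcome, replace(state, trial=state.trial + 1, correct_option=correct,
                            consecutive_correct=streak, reversal_count=reversals)


def play_task(policy, config, rng: np.random.Generator, *,
              subject_id: str = "s0", condition: str = "cond") -> pd.DataFrame:
    """Run an agent through a full task and return its trial table.

    ``policy(option_tuple, history_row_or_None) -> option`` is called once per
    trial; ``history_row`` is the previous trial's (choice, outcome) pair or
    None on the first trial of the run. For the rat task all sessions are
    played back-to-back (the agent's policy sees a continuous stream; the
    task's streak counter resets per session).
    """
    rows = []
    if isinstance(config, HumanTaskConfig):
        state = HumanTaskState(config=config,
                               correct_option=HUMAN_OPTIONS[rng.integers(2)])
        prev = None
        for t in range(config.n_trials):
            choice = policy(HUMAN_OPTIONS, prev)
            correct_before = state.correct_option
            outcome, state = step_human_task(state, choice, rng)
            rows.append((subject_id, condition, 0, t, choice, outcome,
                         correct_before, int(choice == correct_before)))
            prev = (choice, outcome)
    elif isinstance(config, RatTaskConfig):
        prev = None
        start = RAT_OPTIONS[rng.integers(2)]
        for sess in range(config.n_sessions):
            state = RatTaskState(config=config, correct_option=start)
            for t in range(config.n_trials_per_session):
                choice = policy(RAT_OPTIONS, prev)
                correct_before = state.correct_option
                outcome, state = step_rat_task(state, choice, rng)
                rows.append((subject_id, condition, sess, t, choice, outcome,
                             correct_before, int(choice == correct_before)))
                prev = (choice, outcome)
            start = state.correct_option  # contingency carries across days
    else:
        raise TypeError(f"unknown task config {type(config).__name__}")
    return pd.DataFrame(rows, columns=["subject_id", "condition", "session", "trial",
                                       "choice", "outcome", "correct_option",
                                       "chose_correct"])
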