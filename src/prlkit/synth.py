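"""Synthetic PRL experiments: agents drawn from group-level distributions.

A :class:`GroupSpec` describes one experimental condition — how many
subjects, which RL model generates behavior, and the group-level mean and SD
of every model parameter on the *unconstrained* scale (the scale on which
the hierarchical model places its normal population distributions). Agents
are drawn as unconstrained normal deviates and mapped through the inference
module's transforms, so generation and estimation share one parameterisation
and recovered group means are directly comparable to the generating ones.

``simulate_experiment`` plays every agent through a full task (human or rat
variant) and returns a :class:`Dataset` bundling the trial records, the
ground-truth per-subject parameters (retained for parameter-recovery tests,
never shown to the fitter) and provenance (seed and configs). In a
cross-over design the same subjects appear under every condition label: each
subject's deviation from the group mean is drawn once and the per-condition
means shift it, mirroring a within-subject drug design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import to_natural
from .models import MODEL_PARAM_NAMES, AgentParams, LatentState, ModelId, \
    choice_probs, update_state
from .tasks import HumanTaskConfig, RatTaskConfig, play_task

__all__ = ["GroupSpec", "Dataset", "draw_agents", "simulate_experiment",
           "make_policy"]


@dataclass(frozen=True)
class GroupSpec:
    """One condition's generative population.

    ``means``/``sds`` map parameter name -> unconstrained-scale group mean
    and between-subject SD; every parameter of ``model`` must be present.
    """

    label: str
    n_subjects: int
    model: ModelId
    means: dict[str, float]
    sds: dict[str, float]
    design: str = "between"  # "between" | "crossover"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        names = MODEL_PARAM_NAMES[ModelId(self.model)]
        for nm in names:
            if nm not in self.means or nm not in self.sds:
                raise ValueError(f"missing mean/SD for parameter {nm!r}")
            if self.sds[nm] < 0:
                raise ValueError(f"SD for {nm!r} must be >= 0")


@dataclass
class Dataset:
    """Simulated experiment: trial records plus retained ground truth."""

    records: pd.DataFrame
    truth: pd.DataFrame  # subject_id, condition, parameter, value (natural scale)
    provenance: dict = field(default_factory=dict)

    def truth_value(self, subject_id: str, condition: str, parameter: str) -> float:
        t = self.truth
        row = t[(t.subject_id == subject_id) & (t.condition == condition)
                & (t.parameter == parameter)]
        return float(row["value"].iloc[0])


def _agents_from_unconstrained(model: ModelId, label_rows: np.ndarray,
                               names: tuple[str, ...]) -> list[AgentParams]:
    agents = []
    for row in label_rows:
        nat = {nm: float(to_natural(nm, row[i])) for i, nm in enumerate(names)}
        agents.append(AgentParams(model=model, **nat))
    return agents


def draw_agents(spec: GroupSpec, rng: np.random.Generator) -> list[AgentParams]:
    """Per-subject parameter draws: Normal(mean, SD) on the unconstrained
    scale, mapped to the natural scale."""
    names = MODEL_PARAM_NAMES[ModelId(spec.model)]
    mean = np.array([spec.means[nm] for nm in names])
    sd = np.array([spec.sds[nm] for nm in names])
    u = mean + sd * rng.standard_normal((spec.n_subjects, len(names)))
    return _agents_from_unconstrained(ModelId(spec.model), u, names)


def make_policy(agent: AgentParams, options: tuple[str, str],
                rng: np.random.Generator):
    """Stateful choice policy for :func:`prlkit.tasks.play_task`.

    Maintains the agent's latent state across the run (values carry over
    session boundaries, matching how sequences are modelled at fit time).
    """
    state = LatentState()

    def policy(opts, prev):
        nonlocal state
        if prev is not None:
            choice, outcome = prev
            state = update_state(state, options.index(choice), float(outcome), agent)
        p = choice_probs(state, agent)
        return options[int(rng.random() >= p[0])]

    return policy


def simulate_experiment(specs: list[GroupSpec], task_config,
                        rng: np.random.Generator,
                        seed: int | None = None) -> Dataset:
    """Simulate a full multi-condition experiment.

    Between design: each spec contributes its own independent subjects.
    Cross-over design: all specs must agree on ``n_subjects`` and ``model``;
    one unconstrained deviation per subject is drawn from the first spec's
    SDs and reused under every condition's means.
    """
    if not isinstance(task_config, (HumanTaskConfig, RatTaskConfig)):
        raise TypeError(f"unknown task config {type(task_config).__name__}")
    designs = {s.design for s in specs}
    if len(designs) > 1:
        raise ValueError("all specs must share one design")
    design = designs.pop()
    options = task_config.options

    agent_table: list[tuple[str, str, AgentParams]] = []  # (subject, condition, params)
    if design == "between":
        counter = 0
        for spec in specs:
            for agent in draw_agents(spec, rng):
                agent_table.append((f"s{counter:03d}", spec.label, agent))
                counter += 1
    else:
        n = specs[0].n_subjects
        model = ModelId(specs[0].model)
        if any(s.n_subjects != n or ModelId(s.model) is not model for s in specs):
            raise ValueError("crossover specs must share n_subjects and model")
        names = MODEL_PARAM_NAMES[model]
        sd = np.array([specs[0].sds[nm] for nm in names])
        eps = sd * rng.standard_normal((n, len(names)))
        for spec in specs:
            mean = np.array([spec.means[nm] for nm in names])
            for j, agent in enumerate(
                    _agents_from_unconstrained(model, mean + eps, names)):
                agent_table.append((f"s{j:03d}", spec.label, agent))

    frames = []
    truth_rows = []
    for sid, cond, agent in agent_table:
        policy = make_policy(agent, options, rng)
        frames.append(play_task(policy, task_config, rng,
                                subject_id=sid, condition=cond))
        for nm, v in agent.to_dict().items():
            truth_rows.append({"subject_id": sid, "condition": cond,
                               "parameter": nm, "value": v})
    records = pd.concat(frames, ignore_index=True)
    prov = {"seed": seed, "design": design,
            "task": type(task_config).__name__,
            "task_config": {k: getattr(task_config, k)
                            for k in task_config.__dataclass_fields__},
            "groups": [{"label": s.label, "n_subjects": s.n_subjects,
                        "model": ModelId(s.model).value,
                        "means": s.means, "sds": s.sds} for s in specs]}
    return Dataset(records=records, truth=pd.DataFrame(truth_rows), provenance=prov)
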