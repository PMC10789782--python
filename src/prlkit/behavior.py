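"""Conventional task measures, posterior-predictive retrodiction and
parameter recovery.

Win-stay is the probability of repeating the previous choice after a reward;
lose-shift the probability of switching after a punishment. Both are defined
on consecutive trial pairs *within* a session (overnight gaps break the
one-trial-back dependency) and, when a subject has several sessions, are
computed per session and averaged. A conditional with no qualifying pairs is
reported as missing (NaN), never as 0, and missing values are excluded from
group means.

Reversals completed re-derives the serial-reversal counter from the observed
``chose_correct`` stream (eight consecutive correct choices, counter reset on
an error and on each reversal, reset at session boundaries) — the same
semantics as the task simulator, which it must agree with on any simulated
dataset.

``retrodict`` is the posterior-predictive check: draw group-level parameters
from a fitted posterior, simulate fresh subjects per condition (default 40
per group, the scale at which trend-level empirical differences become
detectable), and summarise the conventional measures per condition.
``recovery_experiment`` closes the loop: simulate from known parameters, fit,
and compare per-subject posterior means against the retained truth
(correlation, bias, RMSE per parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (HierarchicalSpec, PosteriorSamples, SamplerSettings,
                        fit, to_natural)
from .models import MODEL_PARAM_NAMES, ModelId
from .synth import Dataset, GroupSpec, simulate_experiment

__all__ = [
    "BehaviorSummary",
    "win_stay_lose_shift",
    "count_reversals",
    "p_optimal_by_trial",
    "summarize_subject",
    "summarize_dataset",
    "retrodict",
    "retrodiction_contrast",
    "recovery_experiment",
]


@dataclass(frozen=True)
class BehaviorSummary:
    """Conventional measures of one subject-condition sequence."""

    win_stay: float  # NaN when no post-reward pairs exist
    lose_shift: float  # NaN when no post-punishment pairs exist
    reversals_completed: int
    p_optimal_by_trial: np.ndarray = field(repr=False, default=None)


def _pairs_within_session(trials: pd.DataFrame):
    """(prev_outcome, stayed) arrays over consecutive within-session pairs."""
    trials = trials.sort_values(["session", "trial"])
    same_session = trials["session"].to_numpy()[1:] == trials["session"].to_numpy()[:-1]
    choice = trials["choice"].to_numpy()
    outcome = trials["outcome"].to_numpy()
    stayed = (choice[1:] == choice[:-1])[same_session]
    prev_outcome = outcome[:-1][same_session]
    return prev_outcome, stayed


def win_stay_lose_shift(trials: pd.DataFrame) -> tuple[float, float]:
    """(win-stay, lose-shift) rates of one subject-condition sequence.

    Computed per session then averaged over sessions; a session with no
    qualifying pairs contributes nothing, and if no session qualifies the
    rate is NaN (missing, not 0).
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    ws_parts, ls_parts = [], []
    for _, sess in trials.groupby("session"):
        if len(sess) < 2:
            continue
        prev, stayed = _pairs_within_session(sess)
        wins = prev > 0
        losses = prev < 0
        if wins.any():
            ws_parts.append(stayed[wins].mean())
        if losses.any():
            ls_parts.append((~stayed[losses]).mean())
    ws = float(np.mean(ws_parts)) if ws_parts else float("nan")
    ls = float(np.mean(ls_parts)) if ls_parts else float("nan")
    return ws, ls


def count_reversals(trials: pd.DataFrame, criterion: int = 8) -> int:
    """Completed reversals in a rat-task sequence from ``chose_correct``.

    A reversal completes whenever ``criterion`` consecutive correct choices
    accumulate; the streak resets on an incorrect choice, on each completed
    reversal, and at session boundaries. Deterministic in the choice stream
    (feedback noise never enters).
    """
    if "chose_correct" not in trials.columns:
        raise ValueError("records must carry the chose_correct column")
    total = 0
    for _, sess in trials.sort_values(["session", "trial"]).groupby("session"):
        streak = 0
        for correct in sess["chose_correct"].to_numpy():
            streak = streak + 1 if correct else 0
            if streak >= criterion:
                total += 1
                streak = 0
    return total


def p_optimal_by_trial(trials: pd.DataFrame) -> np.ndarray:
    """Per-trial probability of choosing the currently correct option,
    averaged over sessions (and subjects, if several are present)."""
    if "chose_correct" not in trials.columns:
        raise ValueError("records must carry the chose_correct column")
    return (trials.groupby("trial")["chose_correct"].mean()
            .sort_index().to_numpy(dtype=float))


def summarize_subject(trials: pd.DataFrame, criterion: int = 8) -> BehaviorSummary:
    ws, ls = win_stay_lose_shift(trials)
    rev = count_reversals(trials, criterion) if "chose_correct" in trials.columns else 0
    popt = (p_optimal_by_trial(trials)
            if "chose_correct" in trials.columns else None)
    return BehaviorSummary(win_stay=ws, lose_shift=ls, reversals_completed=rev,
                           p_optimal_by_trial=popt)


def summarize_dataset(records: pd.DataFrame, criterion: int = 8) -> pd.DataFrame:
    """Per subject-condition summary table of the conventional measures."""
    rows = []
    for (sid, cond), grp in records.groupby(["subject_id", "condition"]):
        s = summarize_subject(grp, criterion)
        rows.append({"subject_id": sid, "condition": cond, "win_stay": s.win_stay,
                     "lose_shift": s.lose_shift,
                     "reversals_completed": s.reversals_completed})
    return pd.DataFrame(rows)


def retrodict(samples: PosteriorSamples, task_config,
              n_sim_subjects: int = 40, rng: np.random.Generator | None = None,
              criterion: int = 8) -> dict[str, pd.DataFrame]:
    """Posterior-predictive simulation of the fitted experiment.

    For every simulated subject a posterior draw of the condition's group
    mean and SD (unconstrained scale) is selected at random, the subject's
    parameters are drawn from that population normal, and a full task is
    played. Returns one per-subject summary table per condition.
    """
    rng = rng or np.random.default_rng()
    spec = samples.spec
    names = spec.param_names
    flat_idx = rng.integers(samples.n_chains * samples.n_draws, size=n_sim_subjects)
    out: dict[str, pd.DataFrame] = {}
    for cond in samples.conditions:
        mu = np.column_stack([
            samples.group_mean_unconstrained(p, cond).reshape(-1) for p in names])
        if spec.design == "between":
            sig = np.column_stack([
                np.exp(samples.latent(f"log_sigma[{cond},{p}]").reshape(-1))
                for p in names])
        else:
            sig = np.column_stack([
                np.exp(samples.latent(f"log_sigma[{p}]").reshape(-1))
                for p in names])
        frames = []
        for j in range(n_sim_subjects):
            u = mu[flat_idx[j]] + sig[flat_idx[j]] * rng.standard_normal(len(names))
            gspec = GroupSpec(label=cond, n_subjects=1, model=spec.model,
                              means=dict(zip(names, u)),
                              sds={p: 0.0 for p in names})
            ds = simulate_experiment([gspec], task_config, rng)
            df = ds.records.assign(subject_id=f"sim{j:03d}")
            frames.append(df)
        sim = pd.concat(frames, ignore_index=True)
        out[cond] = summarize_dataset(sim, criterion)
    return out


def retrodiction_contrast(summary_a: pd.DataFrame, summary_b: pd.DataFrame,
                          measure: str) -> dict:
    """Monte-Carlo contrast of one measure between two retrodicted groups.

    Reports each group's mean with its 95% normal-approximation interval over
    simulated subjects, and the difference A - B.
    """
    a = summary_a[measure].dropna().to_numpy(dtype=float)
    b = summary_b[measure].dropna().to_numpy(dtype=float)
    def ci(x):
        half = 1.96 * x.std(ddof=1) / np.sqrt(x.size)
        return (float(x.mean() - half), float(x.mean() + half))
    return {"mean_a": float(a.mean()), "ci_a": ci(a),
            "mean_b": float(b.mean()), "ci_b": ci(b),
            "diff": float(a.mean() - b.mean()),
            "nonoverlapping": ci(a)[0] > ci(b)[1] or ci(b)[0] > ci(a)[1]}


def recovery_experiment(specs: list[GroupSpec], task_config,
                        settings: SamplerSettings,
                        rng: np.random.Generator) -> dict:
    """Simulate -> fit -> compare per-subject posterior means to truth.

    Returns a report with, per parameter: Pearson correlation between the
    generating value and the posterior subject mean (natural scale), mean
    bias and RMSE; plus the fit's maximum split R-hat and the dataset.
    """
    design = specs[0].design
    model = ModelId(specs[0].model)
    ds = simulate_experiment(specs, task_config, rng)
    spec = HierarchicalSpec(model=model,
                            conditions=tuple(s.label for s in specs),
                            design=design)
    samples = fit(ds.records, spec, settings)
    names = MODEL_PARAM_NAMES[model]
    report: dict = {"max_rhat": samples.max_rhat(), "per_parameter": {},
                    "dataset": ds, "samples": samples}
    truth_piv = ds.truth.pivot_table(index=["subject_id", "condition"],
                                     columns="parameter", values="value")
    for p in names:
        true_vals, est_vals = [], []
        for (sid, cond), row in truth_piv.iterrows():
            post = samples.subject_natural(
                p, sid, cond if design == "crossover" else None)
            true_vals.append(row[p])
            est_vals.append(float(post.mean()))
        t = np.asarray(true_vals)
        e = np.asarray(est_vals)
        r = (float(np.corrcoef(t, e)[0, 1])
             if t.size > 1 and t.std() > 0 and e.std() > 0 else float("nan"))
        report["per_parameter"][p] = {
            "pearson_r": r,
            "bias": float((e - t).mean()),
            "rmse": float(np.sqrt(((e - t) ** 2).mean())),
        }
    return report
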