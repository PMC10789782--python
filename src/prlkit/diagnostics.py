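"""Convergence diagnostics and posterior effect summaries.

Three primitives used throughout the pipeline:

* ``rhat`` — the split-chain potential scale reduction factor. Each chain is
  halved before the between/within variance comparison, so within-chain
  drift registers as non-convergence. Values approach 1 for perfect
  convergence; below 1.2 is a lenient guideline and 1.1 the stringent gate
  used here.
* ``hdi`` — the highest density interval: the narrowest contiguous window of
  sorted draws containing at least the requested fraction of posterior
  mass. Computed on pooled post-warmup draws; ties between equal-width
  windows are broken to the leftmost window (deterministic).
* ``flag_effect`` — the significance shorthand for a group mean difference
  (MD): evaluate HDIs at 95/90/85/80/75% descending and report the first
  level whose interval excludes zero (``***``, ``**``, ``*``, ``..``, ``.``;
  ``-`` when zero lies inside even the 75% HDI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HDI_LEVELS",
    "FLAG_BY_LEVEL",
    "HDIResult",
    "EffectSummary",
    "rhat",
    "hdi",
    "flag_effect",
    "summarize_effect",
    "RHAT_STRINGENT",
    "RHAT_LENIENT",
]

#: HDI probability levels reported for every effect, ascending.
HDI_LEVELS = (0.75, 0.80, 0.85, 0.90, 0.95)

#: Flag per level whose HDI excludes zero (evaluated from 0.95 downward).
FLAG_BY_LEVEL = {0.95: "***", 0.90: "**", 0.85: "*", 0.80: "..", 0.75: "."}

NO_EFFECT_FLAG = "-"

RHAT_STRINGENT = 1.1
RHAT_LENIENT = 1.2


@dataclass(frozen=True)
class HDIResult:
    level: float
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def excludes(self, value: float) -> bool:
        return not (self.lower <= value <= self.upper)


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summary of one condition contrast (MD) on the natural scale."""

    parameter: str
    md_mean: float
    hdis: dict[float, HDIResult]
    flag: str

    def as_row(self) -> dict:
        row: dict = {"parameter": self.parameter, "md_mean": self.md_mean,
                     "flag": self.flag}
        for lv in HDI_LEVELS:
            row[f"hdi{int(lv * 100)}_lower"] = self.hdis[lv].lower
            row[f"hdi{int(lv * 100)}_upper"] = self.hdis[lv].upper
        return row


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_draws) with >= 2 chains and >= 4 draws each.
    Each chain is split in half; R-hat compares between-half-chain and
    within-half-chain variances and is >= 1 up to floating error.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    n_half = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n_half], chains[:, n_half:2 * n_half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0.0 and b <= 0.0:
        raise ValueError("zero total variance: degenerate input")
    if w == 0.0:
        return math.inf
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


def hdi(draws: np.ndarray, level: float) -> HDIResult:
    """Narrowest contiguous interval holding >= ``level`` of the draws.

    The window spans ``ceil(level * n)`` order statistics; among equal-width
    windows the leftmost is returned.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    n = draws.size
    if n < 20:
        raise ValueError("need at least 20 draws for an HDI")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    srt = np.sort(draws)
    k = int(math.ceil(level * n))
    if k >= n:
        return HDIResult(level=level, lower=float(srt[0]), upper=float(srt[-1]))
    widths = srt[k - 1:] - srt[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimiser
    return HDIResult(level=level, lower=float(srt[i]), upper=float(srt[i + k - 1]))


def flag_effect(md_draws: np.ndarray) -> str:
    """Table-style significance flag for an MD posterior.

    The highest HDI level excluding zero wins: ``***`` for 95%, ``**`` for
    90%, ``*`` for 85%, ``..`` for 80%, ``.`` for 75%, and ``-`` when zero is
    inside the 75% HDI.
    """
    for lv in sorted(FLAG_BY_LEVEL, reverse=True):
        if hdi(md_draws, lv).excludes(0.0):
            return FLAG_BY_LEVEL[lv]
    return NO_EFFECT_FLAG


def summarize_effect(parameter: str, md_draws: np.ndarray) -> EffectSummary:
    """MD mean, HDIs at all five levels and the significance flag."""
    md_draws = np.asarray(md_draws, dtype=float).ravel()
    hdis = {lv: hdi(md_draws, lv) for lv in HDI_LEVELS}
    return EffectSummary(parameter=parameter, md_mean=float(md_draws.mean()),
                         hdis=hdis, flag=flag_effect(md_draws))
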