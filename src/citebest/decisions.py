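"""Posterior decision quantities: HDIs, effect sizes, credibility, ROPE.

From a posterior trace this module derives, per posterior draw, the
difference of group means mu1 - mu2, the difference of group standard
deviations, and Cohen's d with the unequal-n pooling

    sigma_pooled = sqrt(((n1 - 1) sigma1^2 + (n2 - 1) sigma2^2) / (n1 + n2 - 2)),

summarizes each by its posterior mean and highest-density interval (HDI),
and applies the HDI/ROPE decision rule: reject equal means when the 95% HDI
of mu1 - mu2 lies entirely on one side of zero; accept equal means when the
effect-size HDI lies entirely inside the region of practical equivalence
(default (-0.2, 0.2)); otherwise remain undecided. The ROPE is used only to
accept the null, never to widen rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .model import PosteriorTrace

__all__ = [
    "Decision",
    "DecisionConfig",
    "ComparisonSummary",
    "hdi",
    "difference_draws",
    "effect_size_draws",
    "credibility_above_zero",
    "decide",
    "summarize_comparison",
    "pairwise_credibility_matrix",
]


class Decision(str, Enum):
    REJECT_H0_GROUP1_HIGHER = "REJECT_H0_GROUP1_HIGHER"
    REJECT_H0_GROUP2_HIGHER = "REJECT_H0_GROUP2_HIGHER"
    ACCEPT_H0 = "ACCEPT_H0"
    UNDECIDED = "UNDECIDED"


@dataclass(frozen=True)
class DecisionConfig:
    """HDI mass and effect-size ROPE bounds for the decision rule."""

    hdi_mass: float = 0.95
    rope: tuple[float, float] = (-0.2, 0.2)

    def __post_init__(self) -> None:
        if not (0 < self.hdi_mass < 1):
            raise ValueError(f"hdi_mass must be in (0, 1), got {self.hdi_mass}")
        if self.rope[0] >= self.rope[1]:
            raise ValueError(f"empty ROPE {self.rope}")


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted samples.

    Assumes a unimodal sample distribution (true of the posterior marginals
    handled here); multimodality is not detected.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 samples for an HDI, got {n}")
    if not (0 < mass < 1):
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def difference_draws(trace: PosteriorTrace, g1, g2) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw mu_g1 - mu_g2 and sigma_g1 - sigma_g2, chain-concatenated.

    Draw pairing is preserved so derived quantities stay internally
    consistent draw by draw.
    """
    i, j = trace.group_index(g1), trace.group_index(g2)
    if i == j:
        raise ValueError("g1 and g2 must differ")
    mu_diff = (trace.mu[:, :, i] - trace.mu[:, :, j]).ravel()
    sd_diff = (trace.sigma[:, :, i] - trace.sigma[:, :, j]).ravel()
    return mu_diff, sd_diff


def effect_size_draws(trace: PosteriorTrace, g1, g2, n1: int, n2: int) -> np.ndarray:
    """Per-draw Cohen's d with unequal-n pooled SD evaluated at that draw."""
    if n1 + n2 <= 2:
        raise ValueError("need n1 + n2 > 2 for the pooled SD")
    i, j = trace.group_index(g1), trace.group_index(g2)
    if i == j:
        raise ValueError("g1 and g2 must differ")
    s1 = trace.sigma[:, :, i].ravel()
    s2 = trace.sigma[:, :, j].ravel()
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return (trace.mu[:, :, i].ravel() - trace.mu[:, :, j].ravel()) / pooled


def credibility_above_zero(samples: np.ndarray) -> float:
    """Percentage of draws strictly above zero (zeros count as not above)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample vector")
    return float(100.0 * np.count_nonzero(x > 0) / x.size)


def decide(
    mu_diff_hdi: tuple[float, float],
    effect_hdi: tuple[float, float],
    cfg: DecisionConfig = DecisionConfig(),
) -> Decision:
    """HDI/ROPE decision on equal group means.

    Rejection looks only at the mean-difference HDI versus zero; acceptance
    requires the effect-size HDI inside the ROPE (inclusive bounds).
    """
    lo, hi = mu_diff_hdi
    if lo > 0:
        return Decision.REJECT_H0_GROUP1_HIGHER
    if hi < 0:
        return Decision.REJECT_H0_GROUP2_HIGHER
    e_lo, e_hi = effect_hdi
    if cfg.rope[0] <= e_lo and e_hi <= cfg.rope[1]:
        return Decision.ACCEPT_H0
    return Decision.UNDECIDED


@dataclass(frozen=True)
class QuantitySummary:
    mean: float
    hdi_low: float
    hdi_high: float
    credibility_above_zero: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "credibility_above_zero": self.credibility_above_zero,
        }


@dataclass(frozen=True)
class ComparisonSummary:
    """Posterior summaries and decision for one pairwise group comparison."""

    group1: str
    group2: str
    n1: int
    n2: int
    mean_diff: QuantitySummary
    sd_diff: QuantitySummary
    effect_size: QuantitySummary
    decision: Decision
    hdi_mass: float
    rope: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "group1": self.group1,
            "group2": self.group2,
            "n1": self.n1,
            "n2": self.n2,
            "mean_diff": self.mean_diff.to_dict(),
            "sd_diff": self.sd_diff.to_dict(),
            "effect_size": self.effect_size.to_dict(),
            "decision": self.decision.value,
            "hdi_mass": self.hdi_mass,
            "rope": list(self.rope),
        }


def _summarize(samples: np.ndarray, mass: float) -> QuantitySummary:
    lo, hi = hdi(samples, mass)
    return QuantitySummary(
        mean=float(np.mean(samples)),
        hdi_low=lo,
        hdi_high=hi,
        credibility_above_zero=credibility_above_zero(samples),
    )


def summarize_comparison(
    trace: PosteriorTrace,
    g1,
    g2,
    cfg: DecisionConfig = DecisionConfig(),
) -> ComparisonSummary:
    """Full pairwise summary: mean/SD differences, effect size, decision."""
    i, j = trace.group_index(g1), trace.group_index(g2)
    n1, n2 = trace.sizes[i], trace.sizes[j]
    mu_diff, sd_diff = difference_draws(trace, i, j)
    d = effect_size_draws(trace, i, j, n1, n2)
    mean_s = _summarize(mu_diff, cfg.hdi_mass)
    sd_s = _summarize(sd_diff, cfg.hdi_mass)
    eff_s = _summarize(d, cfg.hdi_mass)
    return ComparisonSummary(
        group1=trace.labels[i],
        group2=trace.labels[j],
        n1=n1,
        n2=n2,
        mean_diff=mean_s,
        sd_diff=sd_s,
        effect_size=eff_s,
        decision=decide((mean_s.hdi_low, mean_s.hdi_high),
                        (eff_s.hdi_low, eff_s.hdi_high), cfg),
        hdi_mass=cfg.hdi_mass,
        rope=cfg.rope,
    )


def pairwise_credibility_matrix(trace: PosteriorTrace) -> pd.DataFrame:
    """Entry (i, j): % credibility that mu_i - mu_j > 0; diagonal is NaN.

    This is the data behind the multi-group comparison heat map.
    """
    G = trace.n_groups
    if G < 2:
        raise ValueError("need >= 2 groups")
    out = np.full((G, G), np.nan)
    flat = trace.mu.reshape(-1, G)
    for i in range(G):
        for j in range(G):
            if i != j:
                out[i, j] = 100.0 * np.mean(flat[:, i] - flat[:, j] > 0)
    return pd.DataFrame(out, index=list(trace.labels), columns=list(trace.labels))
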