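"""Performance indicators on RTE distributions and scenario comparisons.

Eight global indicators summarise the RTE score distribution of a
scenario, pooling all (area x replicate) cells:

* mean and variance of RTE;
* statistical error (%): average over areas of the relative standard
  error of each area's mean RTE;
* probability (%) of being efficient / inefficient (RTE at / below 1);
* probability (%) of RTE > 0.75;
* statistical stability (%): share of scores unchanged (within a
  tolerance) when every simulated variable value is nudged by a small
  random relative perturbation and the efficiency analysis re-run —
  100% = completely stable;
* normalised Shannon entropy (%) of the score distribution over
  equal-width bins on [0, 1] — 0% = fully homogeneous scores,
  100% = fully heterogeneous.

Scenario comparisons use the Kruskal-Wallis rank test with eta-squared
effect size, and post hoc Mann-Whitney pairs with Bonferroni-adjusted
p-values and rank-biserial effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .montecarlo import relative_se_pct

__all__ = [
    "RTEDistribution",
    "IndicatorSet",
    "ComparisonResult",
    "PairwiseResult",
    "compute_indicators",
    "shannon_entropy_pct",
    "compute_stability",
    "kruskal_wallis",
    "pairwise_mann_whitney",
    "compare_groups",
]


@dataclass
class RTEDistribution:
    """Per-area, per-replicate RTE scores for one scenario and orientation."""

    scenario: str
    orientation: str
    area_ids: list[str]
    scores: np.ndarray  # (n_areas, R)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != len(self.area_ids):
            raise ValueError("scores must be (n_areas, R)")
        if np.isnan(self.scores).any():
            raise ValueError("missing RTE cells")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError("RTE scores must lie in [0, 1]")

    def pooled(self) -> np.ndarray:
        return self.scores.ravel()

    def area_means(self) -> dict[str, float]:
        return dict(zip(self.area_ids, self.scores.mean(axis=1)))


@dataclass
class IndicatorSet:
    scenario: str
    orientation: str
    rte_mean: float
    rte_variance: float
    error_pct: float
    p_efficient_pct: float
    p_inefficient_pct: float
    p_above_075_pct: float
    stability_pct: float  # NaN when stability was not evaluated
    entropy_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rte_mean": self.rte_mean,
            "rte_variance": self.rte_variance,
            "error_pct": self.error_pct,
            "p_efficient_pct": self.p_efficient_pct,
            "p_inefficient_pct": self.p_inefficient_pct,
            "p_above_075_pct": self.p_above_075_pct,
            "stability_pct": self.stability_pct,
            "entropy_pct": self.entropy_pct,
        }


def shannon_entropy_pct(scores: np.ndarray, bins: int = 10) -> float:
    """Normalised Shannon entropy of scores over ``bins`` equal-width bins on [0,1]."""
    if bins < 2:
        raise ValueError("entropy needs >= 2 bins")
    counts, _ = np.histogram(np.asarray(scores).ravel(), bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(100.0 * (-(nz * np.log(nz)).sum()) / math.log(bins))


def compute_indicators(
    dist: RTEDistribution,
    efficient_tol: float = 1e-6,
    high_cut: float = 0.75,
    entropy_bins: int = 10,
    stability_pct: float = float("nan"),
) -> IndicatorSet:
    """The global indicator suite for one scenario/orientation.

    Probabilities pool all (area x replicate) cells.  ``stability_pct`` is
    supplied by :func:`compute_stability` (it needs to re-run the pipeline)
    and defaults to NaN when not evaluated.
    """
    s = dist.scores
    if s.shape[1] < 2:
        raise ValueError("indicators need >= 2 replicates")
    pooled = s.ravel()
    p_eff = 100.0 * float(np.mean(pooled >= 1.0 - efficient_tol))
    return IndicatorSet(
        scenario=dist.scenario,
        orientation=dist.orientation,
        rte_mean=float(pooled.mean()),
        rte_variance=float(pooled.var(ddof=1)),
        error_pct=relative_se_pct(s),
        p_efficient_pct=p_eff,
        p_inefficient_pct=100.0 - p_eff,
        p_above_075_pct=100.0 * float(np.mean(pooled > high_cut)),
        stability_pct=stability_pct,
        entropy_pct=shannon_entropy_pct(pooled, entropy_bins),
    )


def compute_stability(
    values: np.ndarray,
    solve: Callable[[np.ndarray], np.ndarray],
    base_scores: np.ndarray,
    delta: float = 0.01,
    epsilon: float = 0.01,
    seed: int = 0,
) -> float:
    """Sensitivity of RTE to a small relative perturbation of variable values.

    Every simulated value is multiplied by (1 + u), u ~ U(-delta, delta)
    i.i.d., the efficiency analysis is re-run by ``solve`` (values ->
    (n_areas, R) scores), and stability is the percentage of cells whose
    RTE moved by at most ``epsilon``.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0:
        return 100.0  # multiplier is exactly 1: scores cannot move
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9173]))
    perturbed = values * (1.0 + rng.uniform(-delta, delta, size=values.shape))
    new_scores = np.asarray(solve(perturbed))
    if new_scores.shape != base_scores.shape:
        raise ValueError("perturbed scores shape mismatch")
    return float(100.0 * np.mean(np.abs(new_scores - base_scores) <= epsilon))


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, int, float, float]:
    """Kruskal-Wallis H (tie-corrected), df, p, and eta-squared effect size.

    eta^2_H = (H - k + 1) / (n - k).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    k = len(groups)
    n = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*groups)
    eta = (H - k + 1) / (n - k)
    return float(H), k - 1, float(p), float(eta)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    U: float
    p_raw: float
    p_bonferroni: float
    r_biserial: float
    significant: bool


@dataclass
class ComparisonResult:
    kw_H: float
    kw_df: int
    kw_p: float
    eta_sq_H: float
    pairwise: list[PairwiseResult]


def pairwise_mann_whitney(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """All C(k,2) Mann-Whitney tests with Bonferroni adjustment.

    The rank-biserial effect size is |1 - 2U/(n1 n2)| in [0, 1].
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if labels is None:
        labels = [f"G{i + 1}" for i in range(len(groups))]
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in combinations(range(len(groups)), 2):
        a, b = groups[i], groups[j]
        U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        p_adj = min(1.0, float(p) * n_pairs)
        r = abs(1.0 - 2.0 * float(U) / (len(a) * len(b)))
        out.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                U=float(U),
                p_raw=float(p),
                p_bonferroni=p_adj,
                r_biserial=r,
                significant=p_adj < alpha,
            )
        )
    return out


def compare_groups(
    groups: Sequence[np.ndarray], labels: Sequence[str] | None = None, alpha: float = 0.05
) -> ComparisonResult:
    """Kruskal-Wallis omnibus plus the full post hoc pairwise table."""
    H, df, p, eta = kruskal_wallis(groups)
    return ComparisonResult(
        kw_H=H, kw_df=df, kw_p=p, eta_sq_H=eta,
        pairwise=pairwise_mann_whitney(groups, labels, alpha),
    )
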