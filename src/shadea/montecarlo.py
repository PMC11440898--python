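"""Monte Carlo uncertainty engine.

A single cross-sectional observation per area is all that administrative
registries provide, so each observed rate is widened into a statistical
distribution (triangular around the observed value by default) and
replicate datasets are drawn from it.  Replication both propagates input
uncertainty into the efficiency scores and artificially multiplies the
number of observations behind each area's RTE distribution.

Sampling proceeds in batches; after each batch the per-area relative
standard error of the mean RTE is computed and averaged over areas, and
sampling stops once this average statistical error drops below the
configured threshold (default 2.5%) or the replicate cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .dataset import Dataset, DatasetError

__all__ = [
    "DistributionSpec",
    "DistributionSet",
    "ReplicateSet",
    "StoppingRule",
    "ConvergenceResult",
    "build_distributions",
    "sample_replicates",
    "run_until_converged",
]

FAMILIES = ("triangular", "truncated-normal", "point-mass")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one (area, variable) cell."""

    area_id: str
    variable: str
    family: str
    params: tuple[float, ...]  # triangular/trunc-normal: (low, mode, high); point-mass: (value,)

    def mean(self) -> float:
        if self.family == "triangular":
            a, m, b = self.params
            return (a + m + b) / 3.0
        if self.family == "point-mass":
            return self.params[0]
        a, m, b = self.params  # truncated-normal: symmetric bounds around the mode
        return m


@dataclass
class DistributionSet:
    """All cell distributions plus the source dataset (defines shape/order)."""

    source: Dataset
    specs: list[DistributionSpec]
    spread: float
    family: str

    @property
    def variables(self) -> list[str]:
        return [v.name for v in self.source.variables]

    def param_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(low, mode, high) arrays of shape (n_areas, n_vars) in dataset order."""
        n, v = self.source.n_areas, len(self.variables)
        by_cell = {(s.area_id, s.variable): s for s in self.specs}
        low = np.zeros((n, v))
        mode = np.zeros((n, v))
        high = np.zeros((n, v))
        for i, rec in enumerate(self.source.areas):
            for j, var in enumerate(self.variables):
                s = by_cell[(rec.area_id, var)]
                if s.family == "point-mass":
                    low[i, j] = mode[i, j] = high[i, j] = s.params[0]
                else:
                    low[i, j], mode[i, j], high[i, j] = s.params
        return low, mode, high


@dataclass
class ReplicateSet:
    """R sampled datasets stored densely as values[R, n_areas, n_vars]."""

    source: Dataset
    variables: list[str]
    values: np.ndarray
    seed: int

    @property
    def R(self) -> int:
        return self.values.shape[0]

    def replicate_matrix(self, r: int) -> np.ndarray:
        return self.values[r]

    def with_values(self, values: np.ndarray) -> "ReplicateSet":
        return ReplicateSet(self.source, self.variables, values, self.seed)


@dataclass(frozen=True)
class StoppingRule:
    """Stop when the average relative SE of mean RTE falls below the threshold."""

    error_threshold_pct: float = 2.5
    batch_size: int = 100
    max_replicates: int = 500

    def __post_init__(self) -> None:
        if self.error_threshold_pct <= 0:
            raise DatasetError("error threshold must be > 0")
        if not 1 <= self.batch_size <= self.max_replicates:
            raise DatasetError("need 1 <= batch_size <= max_replicates")


@dataclass
class ConvergenceResult:
    replicates: ReplicateSet
    scores: np.ndarray  # (n_areas, R)
    achieved_error_pct: float
    converged: bool


def build_distributions(
    dataset: Dataset, spread: float = 0.2, family: str = "triangular"
) -> DistributionSet:
    """One distribution per (area, variable) from the observed rate.

    ``spread`` is the relative half-width: the support is
    [rate*(1-spread), rate*(1+spread)] floored at 0, with the observed rate
    as the mode.  spread = 0 (or a zero rate) degenerates to a point mass.
    """
    if spread < 0:
        raise DatasetError(f"spread must be >= 0, got {spread}")
    if family not in FAMILIES:
        raise DatasetError(f"unknown family {family!r}; expected one of {FAMILIES}")
    specs: list[DistributionSpec] = []
    for rec in dataset.areas:
        for v in dataset.variables:
            rate = rec.rates[v.name]
            if spread == 0 or rate == 0 or family == "point-mass":
                specs.append(DistributionSpec(rec.area_id, v.name, "point-mass", (rate,)))
            else:
                low = max(0.0, rate * (1.0 - spread))
                high = rate * (1.0 + spread)
                specs.append(DistributionSpec(rec.area_id, v.name, family, (low, rate, high)))
    return DistributionSet(source=dataset, specs=specs, spread=spread, family=family)


def _draw_batch(
    dist: DistributionSet, R: int, rng: np.random.Generator
) -> np.ndarray:
    low, mode, high = dist.param_arrays()
    degenerate = high <= low
    if dist.family == "truncated-normal" and not degenerate.all():
        # symmetric truncated normal on [low, high], sd = quarter-width
        from scipy import stats

        width = np.where(degenerate, 1.0, high - low)
        sd = width / 4.0
        a = (low - mode) / sd
        b = (high - mode) / sd
        draws = stats.truncnorm.rvs(
            a, b, loc=mode, scale=sd, size=(R,) + mode.shape, random_state=rng
        )
    else:
        safe_high = np.where(degenerate, low + 1.0, high)
        draws = rng.triangular(low, np.clip(mode, low, safe_high), safe_high, size=(R,) + mode.shape)
    return np.where(degenerate[None, :, :], mode[None, :, :], draws)


def sample_replicates(dist: DistributionSet, R: int, seed: int) -> ReplicateSet:
    """Draw R replicate datasets; reproducible under a fixed seed."""
    if R < 1:
        raise DatasetError("R must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4021]))
    values = _draw_batch(dist, R, rng)
    return ReplicateSet(source=dist.source, variables=dist.variables, values=values, seed=seed)


def relative_se_pct(scores: np.ndarray) -> float:
    """Average over areas of 100 * (SD_i / sqrt(R)) / mean_i.

    ``scores`` is (n_areas, R).  Returns NaN if any area's mean is 0 —
    the metric is undefined there and the run is flagged non-converged.
    """
    R = scores.shape[1]
    means = scores.mean(axis=1)
    if (means == 0).any():
        return float("nan")
    if R < 2:
        return float("inf")
    sds = scores.std(axis=1, ddof=1)
    return float(np.mean(100.0 * (sds / np.sqrt(R)) / means))


def run_until_converged(
    dist: DistributionSet,
    rule: StoppingRule,
    evaluate: Callable[[ReplicateSet], np.ndarray],
    seed: int,
) -> ConvergenceResult:
    """Draw replicate batches until the mean-RTE statistical error converges.

    ``evaluate`` maps a ReplicateSet batch to an (n_areas, R_batch) matrix
    of RTE scores.  Batches come from one sequential generator, so raising
    ``max_replicates`` only extends the same draw stream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4021]))
    chunks: list[np.ndarray] = []
    score_chunks: list[np.ndarray] = []
    total = 0
    achieved = float("inf")
    converged = False
    while total < rule.max_replicates:
        R = min(rule.batch_size, rule.max_replicates - total)
        batch_values = _draw_batch(dist, R, rng)
        batch = ReplicateSet(dist.source, dist.variables, batch_values, seed)
        scores = np.asarray(evaluate(batch))
        if scores.shape != (dist.source.n_areas, R):
            raise DatasetError(
                f"evaluate returned shape {scores.shape}, expected {(dist.source.n_areas, R)}"
            )
        chunks.append(batch_values)
        score_chunks.append(scores)
        total += R
        all_scores = np.concatenate(score_chunks, axis=1)
        # SD below ~1e-12 on the RTE scale is accumulation noise from
        # summing identical doubles, not sampling variance
        sds = all_scores.std(axis=1, ddof=1) if total >= 2 else None
        if total >= 2 and np.all(sds <= 1e-12):
            achieved = 0.0  # degenerate (e.g. point-mass) distributions
            converged = True
            break
        achieved = relative_se_pct(all_scores)
        if np.isnan(achieved):
            converged = False
            break
        if achieved < rule.error_threshold_pct:
            converged = True
            break
    values = np.concatenate(chunks, axis=0)
    reps = ReplicateSet(dist.source, dist.variables, values, seed)
    scores = np.concatenate(score_chunks, axis=1)
    return ConvergenceResult(reps, scores, achieved, converged)
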