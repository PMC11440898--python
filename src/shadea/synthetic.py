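"""Synthetic SHA datasets with the statistical structure of the Andalusian network.

The generator emulates the published per-variable descriptives (mean, SD,
minimum, maximum over 65 catchment areas) of the Andalusian adult
mental-health network with independent truncated-normal marginals, plus a
one-dimensional latent "management quality" per area that couples service
utilisation (outputs) to the area, so that efficiency analysis on the
synthetic data is non-degenerate.

The truncated normal is parameterised by moment correction: the location
parameter is solved so that the mean of the truncated distribution equals
the target mean (a plain ``truncnorm(loc=mean)`` would be biased wherever
the bounds are asymmetric around the mean).  The scale is kept at the
target SD, so the realised SD is somewhat below target for strongly
truncated variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .dataset import Dataset, DatasetError, SHARecord, VariableSpec, default_registry

__all__ = [
    "MarginalSpec",
    "GeneratorConfig",
    "REFERENCE_MARGINALS",
    "generate",
    "make_fixture",
    "split_capitals",
]


@dataclass(frozen=True)
class MarginalSpec:
    """Target mean/SD and hard bounds for one variable's rate."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise DatasetError(f"infeasible marginal: need min <= mean <= max, got {self}")
        if self.sd <= 0:
            raise DatasetError(f"marginal SD must be > 0, got {self.sd}")


#: Descriptive statistics (mean, SD, min, max) of the 65 Andalusian SHAs,
#: per variable.  Structural rates are per 100,000 adults, utilisation
#: rates per 1,000 adults.
REFERENCE_MARGINALS: dict[str, MarginalSpec] = {
    "availability_o9o10": MarginalSpec(1.43, 0.88, 0.46, 5.36),
    "psychiatrists_o9o10": MarginalSpec(3.72, 1.07, 0.12, 6.30),
    "psychologists_o9o10": MarginalSpec(2.05, 0.77, 0.73, 5.38),
    "nurses_o9o10": MarginalSpec(2.08, 0.78, 0.05, 5.32),
    "assistants_o9o10": MarginalSpec(1.60, 0.88, 0.02, 3.64),
    "nonclinical_o9o10": MarginalSpec(2.81, 1.64, 0.67, 10.67),
    "availability_r2o3": MarginalSpec(0.26, 0.16, 0.12, 0.94),
    "beds_r2": MarginalSpec(6.73, 1.87, 4.32, 11.31),
    "psychiatrists_r2o3": MarginalSpec(1.08, 0.29, 0.77, 1.92),
    "psychologists_r2o3": MarginalSpec(0.23, 0.18, 0.0, 0.94),
    "nurses_r2o3": MarginalSpec(3.04, 1.11, 0.0, 5.66),
    "assistants_r2o3": MarginalSpec(4.19, 1.43, 1.93, 7.54),
    "nonclinical_r2o3": MarginalSpec(1.86, 1.74, 0.67, 9.63),
    "availability_d1d41": MarginalSpec(0.47, 0.11, 0.33, 0.68),
    "places_d1d41": MarginalSpec(11.74, 2.39, 8.29, 16.35),
    "psychiatrists_d1d41": MarginalSpec(0.41, 0.22, 0.13, 0.88),
    "psychologists_d1d41": MarginalSpec(0.50, 0.20, 0.10, 0.75),
    "nurses_d1d41": MarginalSpec(0.69, 0.26, 0.31, 1.42),
    "assistants_d1d41": MarginalSpec(0.89, 0.26, 0.44, 1.25),
    "nonclinical_d1d41": MarginalSpec(1.83, 0.54, 0.78, 2.55),
    "prevalence_o9o10": MarginalSpec(20.03, 5.96, 4.30, 35.05),
    "contacts_o9o10": MarginalSpec(91.91, 37.18, 5.82, 208.46),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    ``coupling_strength`` in [0, 1] sets how strongly a latent per-area
    efficiency drives the output rates: an output baseline draw is
    multiplied by ``1 + coupling * (latent - 0.5)`` with latent ~ U(0,1).
    The default 0.3 gives moderate, clearly detectable coupling without
    pushing outputs against their bounds.
    """

    n_areas: int = 65
    seed: int = 0
    marginals: Mapping[str, MarginalSpec] = field(default_factory=lambda: dict(REFERENCE_MARGINALS))
    coupling_strength: float = 0.3
    n_capitals: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise DatasetError("n_areas must be >= 1")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise DatasetError("coupling_strength must be in [0, 1]")
        for name, m in self.marginals.items():
            if m.max < m.min:
                raise DatasetError(f"marginal {name!r}: max < min")


def _corrected_loc(m: MarginalSpec) -> float:
    """Location for which truncnorm(loc, m.sd, [m.min, m.max]) has mean m.mean."""

    def trunc_mean(loc: float) -> float:
        a = (m.min - loc) / m.sd
        b = (m.max - loc) / m.sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=m.sd)

    lo, hi = m.min - 6 * m.sd, m.max + 6 * m.sd
    return optimize.brentq(lambda loc: trunc_mean(loc) - m.mean, lo, hi, xtol=1e-10)


def _sample_marginal(m: MarginalSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    loc = _corrected_loc(m)
    a = (m.min - loc) / m.sd
    b = (m.max - loc) / m.sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=m.sd, size=n, random_state=rng)


def _calibrate_column(x: np.ndarray, m: MarginalSpec) -> np.ndarray:
    """Shift values within [min, max] so the sample mean hits the target exactly.

    The correction is distributed proportionally to each value's headroom
    toward the needed bound, so no value leaves the support.
    """
    x = x.copy()
    for _ in range(8):
        delta = m.mean - x.mean()
        if abs(delta) < 1e-12:
            break
        head = (m.max - x) if delta > 0 else (x - m.min)
        total = head.sum()
        if total <= 0:
            break
        x += delta * len(x) * head / total
        np.clip(x, m.min, m.max, out=x)
    return x


def generate(config: GeneratorConfig, calibrate_means: bool = False) -> Dataset:
    """Draw a synthetic SHA dataset under ``config``.

    With ``calibrate_means`` the sample mean of every variable is adjusted
    to match its target exactly (values stay within [min, max]); used for
    the deterministic 65-area stand-in datasheet.
    """
    registry = [v for v in default_registry() if v.name in config.marginals]
    missing = set(config.marginals) - {v.name for v in registry}
    if missing:
        raise DatasetError(f"marginals for unregistered variables: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 8561]))
    n = config.n_areas

    # Adult populations: heavy-tailed across areas, like a real region where
    # a few urban areas concentrate most of the adult population.
    pops = np.exp(rng.normal(np.log(90_000.0), 0.55, size=n))
    pops = np.clip(pops, 20_000, 650_000).round()

    latent = rng.uniform(0.0, 1.0, size=n)
    columns: dict[str, np.ndarray] = {}
    for var in registry:
        m = config.marginals[var.name]
        draws = _sample_marginal(m, n, rng)
        if var.role == "output":
            draws = draws * (1.0 + config.coupling_strength * (latent - 0.5))
            np.clip(draws, m.min, m.max, out=draws)
        if calibrate_means:
            draws = _calibrate_column(draws, m)
        columns[var.name] = draws

    denom = {v.name: v.rate_denominator for v in registry}
    areas = []
    for i in range(n):
        area_id = f"SHA{i + 1:03d}"
        rates = {name: float(col[i]) for name, col in columns.items()}
        counts = {name: rates[name] * pops[i] / denom[name] for name in rates}
        areas.append(
            SHARecord(
                area_id=area_id,
                name=f"Catchment area {i + 1}",
                adult_population=float(pops[i]),
                counts=counts,
                rates=rates,
            )
        )
    dataset = Dataset(areas=areas, variables=registry)
    if config.n_capitals:
        dataset = split_capitals(dataset, config.n_capitals, seed=config.seed)
    return dataset


def split_capitals(
    dataset: Dataset,
    n_capitals: int,
    seed: int,
    sizes: Sequence[int] | None = None,
) -> Dataset:
    """Split selected areas into 2-4 sub-areas sharing a ``capital_key``.

    Counts and population are partitioned so that
    :func:`~shadea.dataset.merge_capital_areas` inverts the split exactly.
    Emulates multi-centre capital cities whose intra-urban borders are
    unclear and which are therefore analysed merged.
    """
    if n_capitals > dataset.n_areas:
        raise DatasetError("n_capitals exceeds number of areas")
    if n_capitals == 0:
        return dataset
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    chosen = sorted(rng.choice(dataset.n_areas, size=n_capitals, replace=False).tolist())
    if sizes is None:
        sizes = rng.integers(2, 5, size=n_capitals).tolist()
    if len(sizes) != n_capitals:
        raise DatasetError("sizes must have one entry per capital")
    denom = {v.name: v.rate_denominator for v in dataset.variables}

    out: list[SHARecord] = []
    chosen_set = {idx: k for idx, k in zip(chosen, sizes)}
    for idx, rec in enumerate(dataset.areas):
        if idx not in chosen_set:
            out.append(rec)
            continue
        k = chosen_set[idx]
        w = rng.dirichlet(np.full(k, 5.0))
        pops = np.floor(rec.adult_population * w)
        pops[-1] = rec.adult_population - pops[:-1].sum()
        counts_src = rec.counts or {
            v: rec.rates[v] * rec.adult_population / denom[v] for v in rec.rates
        }
        sub_counts: list[dict[str, float]] = [dict() for _ in range(k)]
        for var, total in counts_src.items():
            parts = [total * pops[j] / rec.adult_population for j in range(k - 1)]
            parts.append(total - sum(parts))
            for j in range(k):
                sub_counts[j][var] = parts[j]
        for j in range(k):
            rates = {var: c / pops[j] * denom[var] for var, c in sub_counts[j].items()}
            out.append(
                SHARecord(
                    area_id=f"{rec.area_id}_{j + 1}",
                    name=f"{rec.name} (centre {j + 1})",
                    adult_population=float(pops[j]),
                    capital_key=rec.area_id,
                    counts=sub_counts[j],
                    rates=rates,
                )
            )
    return Dataset(areas=out, variables=list(dataset.variables))


def make_fixture(name: str) -> Dataset:
    """Hand-built deterministic fixtures.

    * ``tiny3`` — 3 areas, 1 input, 1 output, with known VRS DEA answers.
    * ``frontier4`` — 4 areas, one dominating all others.
    * ``andalusia65`` — seeded 65-area emulation of the Andalusian network
      descriptives, sample means calibrated exactly to the targets.
    """
    if name == "tiny3":
        return _xy_fixture({"A": (2.0, 2.0), "B": (4.0, 4.0), "C": (4.0, 2.0)})
    if name == "frontier4":
        return _xy_fixture({"F1": (1.0, 5.0), "F2": (2.0, 4.0), "F3": (3.0, 3.0), "F4": (4.0, 1.0)})
    if name == "andalusia65":
        return generate(GeneratorConfig(n_areas=65, seed=65), calibrate_means=True)
    raise KeyError(f"unknown fixture {name!r}; expected tiny3, frontier4 or andalusia65")


def _xy_fixture(points: Mapping[str, tuple[float, float]]) -> Dataset:
    variables = [
        VariableSpec("staff", ("O9", "O10"), "input", 100_000, "outpatient"),
        VariableSpec("users", ("O9", "O10"), "output", 1_000, "outpatient"),
    ]
    areas = [
        SHARecord(area_id=k, name=k, adult_population=100_000.0, rates={"staff": x, "users": y})
        for k, (x, y) in points.items()
    ]
    return Dataset(areas=areas, variables=variables)
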