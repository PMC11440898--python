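"""Domain model and I/O for small health catchment area (SHA) data.

An SHA is the analysis unit of a community mental-health network: a
territory served by one reference outpatient centre, possibly with acute
hospital and health day care integrated in the same area.  Two kinds of
variables describe each SHA:

* structural variables (service availability, workforce, beds, places),
  expressed as rates per 100,000 adults — the resource/input side;
* utilisation variables (treated prevalence, frequentation/contacts),
  expressed as rates per 1,000 adults — the outcome/output side.

Care types are identified by DESDE-LTC codes (O9/O10 non-acute outpatient,
O3 acute 24-h physician-covered outpatient, R2 acute hospital residential,
D1 acute day care, D4.1 non-acute high-intensity health day care).  The
codes are metadata attached to each variable; arithmetic only sees rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariableSpec",
    "SHARecord",
    "Dataset",
    "DatasetError",
    "compute_rate",
    "merge_capital_areas",
    "read_dataset",
    "write_dataset",
    "summarize_dataset",
    "default_registry",
]

RATE_RTOL = 1e-9


class DatasetError(ValueError):
    """Raised for schema violations, bad cells, or invalid domain values."""


@dataclass(frozen=True)
class VariableSpec:
    """One registered variable: its care-type codes, role, and denominator."""

    name: str
    desde_codes: tuple[str, ...]
    role: str  # "input" | "output"
    rate_denominator: int  # 100_000 for structural, 1_000 for utilisation
    care_group: str  # "outpatient" | "acute_hospital" | "health_day"

    def __post_init__(self) -> None:
        if self.role not in ("input", "output"):
            raise DatasetError(f"variable {self.name!r}: role must be 'input' or 'output'")
        if self.rate_denominator not in (100_000, 1_000):
            raise DatasetError(f"variable {self.name!r}: denominator must be 100000 or 1000")
        if self.role == "input" and self.rate_denominator != 100_000:
            raise DatasetError(f"structural variable {self.name!r} must use denominator 100000")
        if self.role == "output" and self.rate_denominator != 1_000:
            raise DatasetError(f"utilisation variable {self.name!r} must use denominator 1000")
        if not self.desde_codes:
            raise DatasetError(f"variable {self.name!r}: desde_codes must be non-empty")


@dataclass
class SHARecord:
    """One catchment area: adult population plus per-variable rates.

    ``counts`` (raw numerators) are optional; when present each rate must be
    consistent with count / adult_population x denominator.
    """

    area_id: str
    name: str = ""
    adult_population: float = 0.0
    capital_key: str | None = None
    counts: dict[str, float] | None = None
    rates: dict[str, float] = field(default_factory=dict)

    def validate(self, variables: Sequence[VariableSpec]) -> None:
        if self.adult_population <= 0:
            raise DatasetError(f"area {self.area_id!r}: adult_population must be > 0")
        denom = {v.name: v.rate_denominator for v in variables}
        for var, rate in self.rates.items():
            if rate < 0:
                raise DatasetError(f"area {self.area_id!r}, variable {var!r}: negative rate {rate}")
            if self.counts is not None and var in self.counts:
                expected = self.counts[var] / self.adult_population * denom[var]
                if not math.isclose(rate, expected, rel_tol=RATE_RTOL, abs_tol=1e-12):
                    raise DatasetError(
                        f"area {self.area_id!r}, variable {var!r}: rate {rate} inconsistent "
                        f"with count {self.counts[var]} (expected {expected})"
                    )


@dataclass
class Dataset:
    """Ordered collection of SHA records plus the variable registry."""

    areas: list[SHARecord]
    variables: list[VariableSpec]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        names = {v.name for v in self.variables}
        for rec in self.areas:
            if rec.area_id in seen:
                raise DatasetError(f"duplicate area_id {rec.area_id!r}")
            seen.add(rec.area_id)
            unknown = set(rec.rates) - names
            if unknown:
                raise DatasetError(f"area {rec.area_id!r}: rates for unregistered variables {sorted(unknown)}")
            rec.validate(self.variables)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def rate_matrix(self, variables: Sequence[str] | None = None):
        """Rates as a pandas DataFrame (areas x variables, registry order)."""
        cols = list(variables) if variables is not None else [v.name for v in self.variables]
        data = {c: [rec.rates.get(c, float("nan")) for rec in self.areas] for c in cols}
        return pd.DataFrame(data, index=[rec.area_id for rec in self.areas])


def compute_rate(count: float, adult_population: float, denominator: int) -> float:
    """Raw service count to a population rate (per 100,000 or 1,000 adults)."""
    if adult_population <= 0:
        raise DatasetError(f"adult_population must be positive, got {adult_population}")
    if count < 0:
        raise DatasetError(f"count must be nonnegative, got {count}")
    if denominator not in (100_000, 1_000):
        raise DatasetError(f"denominator must be 100000 or 1000, got {denominator}")
    return count / adult_population * denominator


def merge_capital_areas(dataset: Dataset) -> Dataset:
    """Collapse multi-centre capital cities into single records.

    Records sharing a non-empty ``capital_key`` are merged: populations and
    numerators are summed and rates recomputed from the summed numerators.
    When counts are absent the numerator is recovered as
    rate x population / denominator, i.e. merging is population-weighted,
    never a plain average of rates.  Non-capital records pass through
    unchanged; first-appearance order is kept.
    """
    denom = {v.name: v.rate_denominator for v in dataset.variables}
    merged: list[SHARecord] = []
    groups: dict[str, list[SHARecord]] = {}
    order: list[tuple[str, str]] = []  # ("rec", area_id) or ("group", key)
    for rec in dataset.areas:
        if rec.capital_key:
            if rec.capital_key not in groups:
                groups[rec.capital_key] = []
                order.append(("group", rec.capital_key))
            groups[rec.capital_key].append(rec)
        else:
            order.append(("rec", rec.area_id))

    by_id = {rec.area_id: rec for rec in dataset.areas}
    for kind, key in order:
        if kind == "rec":
            merged.append(by_id[key])
            continue
        members = groups[key]
        pop = sum(m.adult_population for m in members)
        varnames = set().union(*(m.rates.keys() for m in members))
        has_counts = all(m.counts is not None for m in members)
        numerators: dict[str, float] = {}
        for var in varnames:
            total = 0.0
            for m in members:
                if m.counts is not None and var in m.counts:
                    total += m.counts[var]
                else:
                    total += m.rates[var] * m.adult_population / denom[var]
            numerators[var] = total
        rates = {var: compute_rate(num, pop, denom[var]) for var, num in numerators.items()}
        merged.append(
            SHARecord(
                area_id=key,
                name=members[0].name,
                adult_population=pop,
                capital_key=None,
                counts=dict(numerators) if has_counts else None,
                rates=rates,
            )
        )
    return Dataset(areas=merged, variables=list(dataset.variables))


def read_dataset(path: str | Path, schema: Sequence[VariableSpec]) -> Dataset:
    """Load a delimited-text SHA table validated against ``schema``.

    The file must carry a header naming ``area_id``, ``adult_population``
    and one column per schema variable.  Violations are reported with the
    offending row/column.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: empty file") from None
    if frame.empty:
        raise DatasetError(f"{path}: no data rows")
    required = ["area_id", "adult_population"] + [v.name for v in schema]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")

    areas: list[SHARecord] = []
    for i, row in frame.iterrows():
        rates = {}
        for v in schema:
            val = row[v.name]
            if pd.isna(val):
                raise DatasetError(f"{path}: row {i}, column {v.name!r}: missing value")
            if val < 0:
                raise DatasetError(f"{path}: row {i}, column {v.name!r}: negative rate {val}")
            rates[v.name] = float(val)
        cap = row.get("capital_key")
        areas.append(
            SHARecord(
                area_id=str(row["area_id"]),
                name=str(row["name"]) if "name" in frame.columns and not pd.isna(row["name"]) else "",
                adult_population=float(row["adult_population"]),
                capital_key=None if cap is None or pd.isna(cap) or cap == "" else str(cap),
                rates=rates,
            )
        )
    try:
        return Dataset(areas=areas, variables=list(schema))
    except DatasetError as exc:
        raise DatasetError(f"{path}: {exc}") from None


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the CSV dialect read back by :func:`read_dataset`."""
    rows = []
    for rec in dataset.areas:
        row: dict[str, object] = {
            "area_id": rec.area_id,
            "name": rec.name,
            "capital_key": rec.capital_key or "",
            "adult_population": rec.adult_population,
        }
        for v in dataset.variables:
            row[v.name] = rec.rates[v.name]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def summarize_dataset(dataset: Dataset) -> pd.DataFrame:
    """Per-variable mean, sample SD, coefficient of variation (%), max, min."""
    if dataset.n_areas < 2:
        raise DatasetError("summary requires at least 2 areas (sample SD undefined)")
    frame = dataset.rate_matrix()
    mean = frame.mean()
    sd = frame.std(ddof=1)
    cv = 100.0 * sd / mean.where(mean != 0)
    out = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "cv_pct": cv.fillna(0.0),
            "max": frame.max(),
            "min": frame.min(),
        }
    )
    out.index.name = "variable"
    return out


def default_registry() -> list[VariableSpec]:
    """The variable registry of the Andalusian adult mental-health network.

    Structural variables (inputs, per 100,000 adults) cover non-acute
    outpatient care (O9-O10), acute hospital care (R2-O3) and health day
    care (D1-D4.1); utilisation variables (outputs, per 1,000 adults) are
    treated prevalence and frequentation in outpatient care.
    """

    def inp(name: str, codes: tuple[str, ...], group: str) -> VariableSpec:
        return VariableSpec(name, codes, "input", 100_000, group)

    o = ("O9", "O10")
    r = ("R2", "O3")
    d = ("D1", "D4.1")
    return [
        inp("availability_o9o10", o, "outpatient"),
        inp("psychiatrists_o9o10", o, "outpatient"),
        inp("psychologists_o9o10", o, "outpatient"),
        inp("nurses_o9o10", o, "outpatient"),
        inp("assistants_o9o10", o, "outpatient"),
        inp("nonclinical_o9o10", o, "outpatient"),
        inp("availability_r2o3", r, "acute_hospital"),
        inp("beds_r2", ("R2",), "acute_hospital"),
        inp("psychiatrists_r2o3", r, "acute_hospital"),
        inp("psychologists_r2o3", r, "acute_hospital"),
        inp("nurses_r2o3", r, "acute_hospital"),
        inp("assistants_r2o3", r, "acute_hospital"),
        inp("nonclinical_r2o3", r, "acute_hospital"),
        inp("availability_d1d41", d, "health_day"),
        inp("places_d1d41", d, "health_day"),
        inp("psychiatrists_d1d41", d, "health_day"),
        inp("psychologists_d1d41", d, "health_day"),
        inp("nurses_d1d41", d, "health_day"),
        inp("assistants_d1d41", d, "health_day"),
        inp("nonclinical_d1d41", d, "health_day"),
        VariableSpec("prevalence_o9o10", o, "output", 1_000, "outpatient"),
        VariableSpec("contacts_o9o10", o, "output", 1_000, "outpatient"),
    ]
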