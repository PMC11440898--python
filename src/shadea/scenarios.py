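"""Analysis scenarios: expert-chosen input/output variable combinations.

DEA cannot discriminate with too many inputs and outputs relative to the
number of units, so the system is analysed through four nested scenarios
describing successive integration of care types around the outpatient
baseline:

* S1 — non-acute outpatient care only (O9-O10): availability and
  workforce (psychiatrists, nurses, psychologists, non-clinical staff);
* S2 — S1 plus acute hospital care (R2-O3): adds availability, beds in
  R2, and the R2-O3 workforce;
* S3 — S1 plus health day care (D1-D4.1): adds availability, places, and
  the D1-D4.1 workforce;
* S4 — all three types of care together (union of S2 and S3 inputs).

All scenarios share the same outputs: treated prevalence and
frequentation (contacts) in outpatient care, per 1,000 adults.

A scenario input entry may be a single variable name or a tuple of names;
tuples are summed into one DEA input column (used to aggregate the four
workforce categories into a single workforce-capacity input when DEA
dimensionality is a concern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dea import DEAInstance
from .dataset import Dataset, DatasetError

__all__ = [
    "ScenarioSpec",
    "ScenarioError",
    "default_scenarios",
    "load_scenarios",
    "save_scenarios",
    "build_instance",
    "build_instance_from_matrix",
]

InputEntry = "str | tuple[str, ...]"


class ScenarioError(ValueError):
    """Scenario configuration or assembly error."""


def _flatten(entries) -> list[str]:
    flat: list[str] = []
    for e in entries:
        if isinstance(e, str):
            flat.append(e)
        else:
            flat.extend(e)
    return flat


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    name: str
    input_variables: tuple
    output_variables: tuple[str, ...]

    def __post_init__(self) -> None:
        ins = _flatten(self.input_variables)
        outs = list(self.output_variables)
        if not outs:
            raise ScenarioError(f"scenario {self.id}: outputs must be non-empty")
        if not ins:
            raise ScenarioError(f"scenario {self.id}: inputs must be non-empty")
        overlap = set(ins) & set(outs)
        if overlap:
            raise ScenarioError(f"scenario {self.id}: variables both input and output: {sorted(overlap)}")
        if len(ins) != len(set(ins)):
            raise ScenarioError(f"scenario {self.id}: duplicate input variables")

    @property
    def all_variables(self) -> list[str]:
        return _flatten(self.input_variables) + list(self.output_variables)

    def validate_against(self, registry_names: set[str]) -> None:
        unknown = set(self.all_variables) - registry_names
        if unknown:
            raise ScenarioError(f"scenario {self.id}: unknown variables {sorted(unknown)}")


_WORKFORCE = ("psychiatrists", "nurses", "psychologists", "nonclinical")


def _workforce(suffixes: Sequence[str], aggregate: bool):
    cols = [f"{cat}_{s}" for cat in _WORKFORCE for s in suffixes]
    return [tuple(cols)] if aggregate else cols


def default_scenarios(aggregate_workforce: bool = False) -> list[ScenarioSpec]:
    """The four care-integration scenarios over the default registry.

    ``aggregate_workforce`` sums the four workforce categories into one
    input column per scenario instead of keeping them separate.
    """
    outputs = ("prevalence_o9o10", "contacts_o9o10")

    def spec(sid, name, inputs):
        return ScenarioSpec(sid, name, tuple(inputs), outputs)

    s1_inputs = ["availability_o9o10"] + _workforce(["o9o10"], aggregate_workforce)
    s2_inputs = (
        ["availability_o9o10", "availability_r2o3", "beds_r2"]
        + _workforce(["o9o10", "r2o3"], aggregate_workforce)
    )
    s3_inputs = (
        ["availability_o9o10", "availability_d1d41", "places_d1d41"]
        + _workforce(["o9o10", "d1d41"], aggregate_workforce)
    )
    s4_inputs = (
        ["availability_o9o10", "availability_r2o3", "availability_d1d41", "beds_r2", "places_d1d41"]
        + _workforce(["o9o10", "r2o3", "d1d41"], aggregate_workforce)
    )
    return [
        spec("S1", "Non-acute outpatient care (baseline)", s1_inputs),
        spec("S2", "Baseline + acute hospital care", s2_inputs),
        spec("S3", "Baseline + health day care", s3_inputs),
        spec("S4", "Baseline + acute hospital + health day care", s4_inputs),
    ]


def load_scenarios(config) -> list[ScenarioSpec]:
    """Scenarios from a YAML/JSON path or an already-parsed mapping."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    specs = []
    for sc in config["scenarios"]:
        inputs = tuple(tuple(e) if isinstance(e, (list, tuple)) else e for e in sc["inputs"])
        specs.append(
            ScenarioSpec(
                id=sc["id"],
                name=sc.get("name", sc["id"]),
                input_variables=inputs,
                output_variables=tuple(sc["outputs"]),
            )
        )
    ids = [s.id for s in specs]
    if len(ids) != len(set(ids)):
        raise ScenarioError("duplicate scenario ids")
    return specs


def save_scenarios(specs: Sequence[ScenarioSpec], path: str | Path) -> None:
    cfg = {
        "scenarios": [
            {
                "id": s.id,
                "name": s.name,
                "inputs": [list(e) if isinstance(e, tuple) else e for e in s.input_variables],
                "outputs": list(s.output_variables),
            }
            for s in specs
        ]
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def build_instance_from_matrix(
    scenario: ScenarioSpec,
    dmu_ids: Sequence[str],
    values: np.ndarray,
    variables: Sequence[str],
    epsilon_floor: float = 0.001,
) -> DEAInstance:
    """Assemble a DEA instance from an (n_areas x n_vars) value matrix."""
    col = {v: j for j, v in enumerate(variables)}
    missing = [v for v in scenario.all_variables if v not in col]
    if missing:
        raise ScenarioError(f"scenario {scenario.id}: replicate missing variables {missing}")
    x_cols = []
    for entry in scenario.input_variables:
        if isinstance(entry, str):
            x_cols.append(values[:, col[entry]])
        else:
            x_cols.append(values[:, [col[v] for v in entry]].sum(axis=1))
    X = np.maximum(np.column_stack(x_cols), epsilon_floor)
    Y = np.column_stack([values[:, col[v]] for v in scenario.output_variables])
    return DEAInstance(dmu_ids=list(dmu_ids), X=X, Y=Y)


def build_instance(
    scenario: ScenarioSpec, replicate: Dataset, epsilon_floor: float = 0.001
) -> DEAInstance:
    """Assemble a DEA instance from one (transformed) replicate dataset."""
    variables = [v.name for v in replicate.variables]
    values = replicate.rate_matrix().to_numpy()
    ids = [rec.area_id for rec in replicate.areas]
    return build_instance_from_matrix(scenario, ids, values, variables, epsilon_floor)
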