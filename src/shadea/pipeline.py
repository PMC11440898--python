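"""End-to-end orchestration: simulate -> interpret -> DEA -> indicators -> maps.

``run_full`` executes, for every scenario and orientation: Monte Carlo
replication of the (capital-merged) dataset, knowledge-base transformation
of each replicate, per-replicate VRS DEA, the indicator suite (including
the stability re-run), scenario comparisons, and three-level geographic
classification.  Everything is written to a run directory as CSV/JSON and
is byte-reproducible from the manifest seed.

Classification thresholds follow the convention used for mapping mental
health system efficiency: mean RTE <= 0.75 is "low", (0.75, 0.9] is
"medium", > 0.9 is "high".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import dea
from .dataset import Dataset, DatasetError, merge_capital_areas, summarize_dataset
from .fuzzy import KnowledgeBase, default_knowledge_base, transform_replicates
from .indicators import (
    ComparisonResult,
    IndicatorSet,
    RTEDistribution,
    compare_groups,
    compute_indicators,
    compute_stability,
)
from .montecarlo import (
    ConvergenceResult,
    ReplicateSet,
    StoppingRule,
    build_distributions,
    run_until_converged,
)
from .scenarios import ScenarioSpec, build_instance_from_matrix, default_scenarios
from .synthetic import MarginalSpec

__all__ = [
    "RTELevelRule",
    "LevelClassification",
    "PipelineConfig",
    "RunResult",
    "classify_levels",
    "export_geojson",
    "run_full",
    "compare_scenarios",
    "kb_for_dataset",
]

LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class RTELevelRule:
    """Three-level mean-RTE classification with closed upper bounds on low/medium."""

    low_max: float = 0.75
    medium_max: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.low_max < self.medium_max < 1.0:
            raise ValueError("need 0 < low_max < medium_max < 1")

    def level(self, mean_rte: float) -> str:
        if not 0.0 <= mean_rte <= 1.0:
            raise ValueError(f"mean RTE must be in [0, 1], got {mean_rte}")
        if mean_rte <= self.low_max:
            return "low"
        if mean_rte <= self.medium_max:
            return "medium"
        return "high"


@dataclass
class LevelClassification:
    levels: dict[str, str]  # area_id -> level
    counts: dict[str, int]
    percentages: dict[str, float]


def classify_levels(
    mean_rte_per_area: Mapping[str, float], rule: RTELevelRule = RTELevelRule()
) -> LevelClassification:
    """Assign each area a low/medium/high RTE level plus counts and percentages."""
    levels = {a: rule.level(m) for a, m in mean_rte_per_area.items()}
    counts = {lv: sum(1 for v in levels.values() if v == lv) for lv in LEVELS}
    n = max(1, len(levels))
    pct = {lv: 100.0 * c / n for lv, c in counts.items()}
    return LevelClassification(levels=levels, counts=counts, percentages=pct)


def export_geojson(
    geo: Mapping | str | Path,
    means: Mapping[str, float],
    levels: Mapping[str, str],
    join_key: str = "area_id",
    scenario: str | None = None,
) -> tuple[dict, list[str], list[str]]:
    """Annotate polygon features with rte_mean / rte_level properties.

    Returns (annotated GeoJSON, areas with no matching feature, feature
    keys with no matching area).  Nothing is silently dropped.
    """
    if isinstance(geo, (str, Path)):
        try:
            geo = json.loads(Path(geo).read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed GeoJSON: {exc}") from None
    if not isinstance(geo, Mapping) or geo.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = {"type": "FeatureCollection", "features": []}
    matched: set[str] = set()
    unmatched_features: list[str] = []
    for feat in geo.get("features", []):
        props = dict(feat.get("properties") or {})
        key = props.get(join_key)
        new = dict(feat)
        if key in means:
            matched.add(key)
            props["rte_mean"] = float(means[key])
            props["rte_level"] = levels[key]
            if scenario is not None:
                props["scenario"] = scenario
        else:
            unmatched_features.append(str(key))
        new["properties"] = props
        out["features"].append(new)
    unmatched_areas = sorted(set(means) - matched)
    return out, unmatched_areas, unmatched_features


def kb_for_dataset(dataset: Dataset, epsilon_floor: float = 0.001) -> KnowledgeBase:
    """Default knowledge base fitted to a dataset's own observed descriptives.

    Used when the dataset does not carry the reference registry; same
    shapes as the shipped default (rising transforms for outputs, unimodal
    for inputs) with anchors at the observed min/mean/max.
    """
    summary = summarize_dataset(dataset)
    marginals = {}
    roles = {v.name: v.role for v in dataset.variables}
    for var in summary.index:
        row = summary.loc[var]
        sd = row["sd"] if row["sd"] > 0 else max(1e-6, 0.1 * abs(row["mean"]) + 1e-6)
        lo, hi = row["min"], row["max"]
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        mean = min(max(row["mean"], lo), hi)
        marginals[var] = MarginalSpec(mean=mean, sd=sd, min=max(0.0, lo), max=hi)
    return default_knowledge_base(marginals=marginals, roles=roles, epsilon_floor=epsilon_floor)


@dataclass
class PipelineConfig:
    spread: float = 0.2
    family: str = "triangular"
    stopping: StoppingRule = field(default_factory=StoppingRule)
    orientations: tuple[str, ...] = ("input", "output")
    entropy_bins: int = 10
    efficient_tol: float = 1e-6
    high_cut: float = 0.75
    level_rule: RTELevelRule = field(default_factory=RTELevelRule)
    stability_delta: float = 0.01
    stability_epsilon: float = 0.01
    stability_max_replicates: int = 50  # stability re-solves this many replicates at most
    evaluate_stability: bool = True


@dataclass
class RunResult:
    out_dir: Path
    distributions: dict[tuple[str, str], RTEDistribution]  # (scenario, orientation)
    indicators: dict[tuple[str, str], IndicatorSet]
    comparisons: dict[str, ComparisonResult]  # per orientation
    classifications: dict[tuple[str, str], LevelClassification]
    achieved_errors: dict[tuple[str, str], float]
    converged: dict[tuple[str, str], bool]
    manifest: dict


def _child_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def _scenario_evaluator(
    kb: KnowledgeBase, scenario: ScenarioSpec, orientation: str
) -> Callable[[ReplicateSet], np.ndarray]:
    def evaluate(reps: ReplicateSet) -> np.ndarray:
        transformed = transform_replicates(kb, reps)
        return _solve_values(transformed, kb, scenario, orientation, already_transformed=True)

    return evaluate


def _solve_values(
    reps: ReplicateSet,
    kb: KnowledgeBase,
    scenario: ScenarioSpec,
    orientation: str,
    already_transformed: bool = False,
) -> np.ndarray:
    if not already_transformed:
        reps = transform_replicates(kb, reps)
    ids = [rec.area_id for rec in reps.source.areas]
    cols = np.empty((len(ids), reps.R))
    for r in range(reps.R):
        inst = build_instance_from_matrix(
            scenario, ids, reps.values[r], reps.variables, kb.epsilon_floor
        )
        cols[:, r] = [res.rte for res in dea.solve_all(inst, orientation)]
    return cols


def run_full(
    dataset: Dataset,
    seed: int,
    out_dir: str | Path,
    kb: KnowledgeBase | None = None,
    scenarios: Sequence[ScenarioSpec] | None = None,
    config: PipelineConfig | None = None,
) -> RunResult:
    """Execute the whole pipeline and persist results under ``out_dir``.

    Deterministic under a fixed seed: two runs write byte-identical RTE
    files.  Any stage failure aborts with a stage-named error.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    merged = merge_capital_areas(dataset)
    varnames = {v.name for v in merged.variables}
    if kb is None:
        from .synthetic import REFERENCE_MARGINALS

        kb = (
            default_knowledge_base()
            if varnames <= set(REFERENCE_MARGINALS)
            else kb_for_dataset(merged)
        )
    if scenarios is None:
        scenarios = default_scenarios()
    for sc in scenarios:
        sc.validate_against(varnames)
    missing_kb = varnames - set(kb.target_variables)
    if missing_kb:
        raise DatasetError(f"stage fuzzy: knowledge base does not cover {sorted(missing_kb)}")

    dist = build_distributions(merged, spread=config.spread, family=config.family)
    area_ids = [rec.area_id for rec in merged.areas]

    distributions: dict[tuple[str, str], RTEDistribution] = {}
    indicators: dict[tuple[str, str], IndicatorSet] = {}
    classifications: dict[tuple[str, str], LevelClassification] = {}
    achieved: dict[tuple[str, str], float] = {}
    converged: dict[tuple[str, str], bool] = {}

    for si, scenario in enumerate(scenarios):
        for oi, orientation in enumerate(config.orientations):
            key = (scenario.id, orientation)
            run_seed = _child_seed(seed, si, oi)
            try:
                conv = run_until_converged(
                    dist,
                    config.stopping,
                    _scenario_evaluator(kb, scenario, orientation),
                    seed=run_seed,
                )
            except Exception as exc:
                raise RuntimeError(f"stage montecarlo/dea [{scenario.id}/{orientation}]: {exc}") from exc
            rte = RTEDistribution(scenario.id, orientation, area_ids, conv.scores)
            distributions[key] = rte
            achieved[key] = conv.achieved_error_pct
            converged[key] = conv.converged

            stability = float("nan")
            if config.evaluate_stability:
                keep = min(conv.replicates.R, config.stability_max_replicates)
                sub = conv.replicates.with_values(conv.replicates.values[:keep])
                stability = compute_stability(
                    sub.values,
                    lambda vals: _solve_values(sub.with_values(vals), kb, scenario, orientation),
                    conv.scores[:, :keep],
                    delta=config.stability_delta,
                    epsilon=config.stability_epsilon,
                    seed=run_seed,
                )
            indicators[key] = compute_indicators(
                rte,
                efficient_tol=config.efficient_tol,
                high_cut=config.high_cut,
                entropy_bins=config.entropy_bins,
                stability_pct=stability,
            )
            classifications[key] = classify_levels(rte.area_means(), config.level_rule)

            frame = pd.DataFrame(
                {
                    "area_id": np.repeat(area_ids, rte.scores.shape[1]),
                    "replicate": np.tile(np.arange(rte.scores.shape[1]), len(area_ids)),
                    "scenario": scenario.id,
                    "orientation": orientation,
                    "rte": rte.scores.ravel(),
                    "efficient": (rte.scores >= 1.0 - config.efficient_tol).ravel(),
                }
            )
            frame.to_csv(out_dir / f"rte_{scenario.id}_{orientation}.csv", index=False)

    comparisons: dict[str, ComparisonResult] = {}
    if len(scenarios) >= 2:
        for orientation in config.orientations:
            groups = [distributions[(sc.id, orientation)].pooled() for sc in scenarios]
            comparisons[orientation] = compare_groups(groups, [sc.id for sc in scenarios])

    _write_tables(out_dir, scenarios, config, indicators, comparisons, classifications)
    manifest = {
        "seed": seed,
        "package_version": _pkg_version("shadea"),
        "n_areas": merged.n_areas,
        "n_areas_raw": dataset.n_areas,
        "scenarios": [sc.id for sc in scenarios],
        "orientations": list(config.orientations),
        "spread": config.spread,
        "family": config.family,
        "stopping": {
            "error_threshold_pct": config.stopping.error_threshold_pct,
            "batch_size": config.stopping.batch_size,
            "max_replicates": config.stopping.max_replicates,
        },
        "epsilon_floor": kb.epsilon_floor,
        "level_rule": {"low_max": config.level_rule.low_max, "medium_max": config.level_rule.medium_max},
        "replicates": {f"{k[0]}/{k[1]}": int(distributions[k].scores.shape[1]) for k in distributions},
        "achieved_error_pct": {f"{k[0]}/{k[1]}": achieved[k] for k in achieved},
        "converged": {f"{k[0]}/{k[1]}": converged[k] for k in converged},
        "knowledge_base": kb.to_config(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(
        out_dir=out_dir,
        distributions=distributions,
        indicators=indicators,
        comparisons=comparisons,
        classifications=classifications,
        achieved_errors=achieved,
        converged=converged,
        manifest=manifest,
    )


def _write_tables(out_dir, scenarios, config, indicators, comparisons, classifications) -> None:
    rows = []
    for (sid, orientation), ind in indicators.items():
        row = {"scenario": sid, "orientation": orientation}
        row.update(ind.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "indicators.csv", index=False)

    comp_rows = []
    for orientation, comp in comparisons.items():
        for pr in comp.pairwise:
            comp_rows.append(
                {
                    "orientation": orientation,
                    "kw_H": comp.kw_H,
                    "kw_df": comp.kw_df,
                    "kw_p": comp.kw_p,
                    "eta_sq_H": comp.eta_sq_H,
                    "pair": f"{pr.pair[0]} vs {pr.pair[1]}",
                    "U": pr.U,
                    "p_raw": pr.p_raw,
                    "p_bonferroni": pr.p_bonferroni,
                    "r_biserial": pr.r_biserial,
                    "significant": pr.significant,
                }
            )
    pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)

    cls_rows = []
    for (sid, orientation), cls in classifications.items():
        for lv in LEVELS:
            cls_rows.append(
                {
                    "scenario": sid,
                    "orientation": orientation,
                    "level": lv,
                    "count": cls.counts[lv],
                    "pct": cls.percentages[lv],
                }
            )
    pd.DataFrame(cls_rows).to_csv(out_dir / "classification.csv", index=False)


def compare_scenarios(run_dir: str | Path, orientation: str = "input") -> ComparisonResult:
    """Recompute the scenario comparison from a run directory's RTE CSVs."""
    run_dir = Path(run_dir)
    files = sorted(run_dir.glob(f"rte_*_{orientation}.csv"))
    if len(files) < 2:
        raise ValueError(f"need >= 2 scenario RTE files in {run_dir} for orientation {orientation!r}")
    groups, labels, shapes = [], [], set()
    for f in files:
        frame = pd.read_csv(f, float_precision="round_trip")
        groups.append(frame["rte"].to_numpy())
        labels.append(str(frame["scenario"].iloc[0]))
        shapes.add(len(frame))
    if len(shapes) > 1:
        raise ValueError(f"mismatched RTE shapes across scenarios: {sorted(shapes)}")
    return compare_groups(groups, labels)
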