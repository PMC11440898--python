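"""Rule-based piecewise-linear interpretation of service rates.

The balanced-care knowledge base judges whether a raw rate (e.g. 3.15 day
places per 100,000 adults) is *appropriate* for a community mental-health
system.  IF...THEN rules dispatch, per variable and conditional on the
area's simulated values, a piecewise-linear transform mapping the rate to
an appropriateness value in [0, 1].  Transforms may rise, fall, or contain
several desirable/undesirable zones; they are not restricted to a single
monotone segment.

This is rule-selected value transformation, not Mamdani/Sugeno fuzzy-set
arithmetic: no membership overlap or defuzzification is involved.

Results are floored at a small epsilon so downstream DEA inputs stay
strictly positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .montecarlo import ReplicateSet
from .synthetic import REFERENCE_MARGINALS, MarginalSpec

__all__ = [
    "TransformFunction",
    "Condition",
    "Antecedent",
    "FuzzyRule",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "apply_transform",
    "evaluate_rules",
    "transform_replicates",
    "default_knowledge_base",
]


class KnowledgeBaseError(ValueError):
    """Configuration, coverage, or ambiguity error in the knowledge base."""


@dataclass(frozen=True)
class TransformFunction:
    """Piecewise-linear map rate -> appropriateness, clamped outside anchors."""

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise KnowledgeBaseError("transform needs at least one anchor")
        xs = [a[0] for a in self.anchors]
        ys = [a[1] for a in self.anchors]
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise KnowledgeBaseError(f"anchor x values must be strictly increasing, got {xs}")
        if any(not 0.0 <= y <= 1.0 for y in ys):
            raise KnowledgeBaseError(f"anchor y values must lie in [0, 1], got {ys}")

    def __call__(self, x):
        xs = np.array([a[0] for a in self.anchors])
        ys = np.array([a[1] for a in self.anchors])
        return np.interp(x, xs, ys)  # np.interp clamps to first/last y


def apply_transform(t: TransformFunction, x: float) -> float:
    """Interpolate ``x`` through ``t`` (clamped below/above the anchor range)."""
    if x < 0:
        raise KnowledgeBaseError(f"rates are nonnegative, got {x}")
    return float(t(x))


_COND_RE = re.compile(r"^\s*(\w+)\s*(<=|>=|<|>|==)\s*([-+0-9.eE]+)\s*$")
_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
    "==": np.isclose,
}


@dataclass(frozen=True)
class Condition:
    variable: str
    op: str
    value: float

    @classmethod
    def parse(cls, text: str) -> "Condition":
        m = _COND_RE.match(text)
        if not m:
            raise KnowledgeBaseError(f"cannot parse condition {text!r}")
        return cls(m.group(1), m.group(2), float(m.group(3)))

    def holds(self, values: Mapping[str, float]) -> bool:
        if self.variable not in values:
            raise KnowledgeBaseError(f"condition references missing variable {self.variable!r}")
        return bool(_OPS[self.op](values[self.variable], self.value))

    def __str__(self) -> str:
        return f"{self.variable} {self.op} {self.value:g}"


@dataclass(frozen=True)
class Antecedent:
    """Conjunction ("all") or disjunction ("any") of threshold comparisons."""

    mode: str
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("all", "any"):
            raise KnowledgeBaseError(f"antecedent mode must be 'all' or 'any', got {self.mode!r}")

    @classmethod
    def parse(cls, obj) -> "Antecedent | None":
        if obj is None:
            return None
        if isinstance(obj, str):
            return cls("all", (Condition.parse(obj),))
        if isinstance(obj, Sequence):
            return cls("all", tuple(Condition.parse(c) for c in obj))
        if isinstance(obj, Mapping) and len(obj) == 1:
            (mode, conds), = obj.items()
            return cls(mode, tuple(Condition.parse(c) for c in conds))
        raise KnowledgeBaseError(f"cannot parse antecedent {obj!r}")

    def holds(self, values: Mapping[str, float]) -> bool:
        agg = all if self.mode == "all" else any
        return agg(c.holds(values) for c in self.conditions)

    def to_config(self):
        return {self.mode: [str(c) for c in self.conditions]}


@dataclass(frozen=True)
class FuzzyRule:
    """IF antecedent THEN apply ``transform`` to ``target_variable``."""

    target_variable: str
    transform: TransformFunction
    antecedent: Antecedent | None = None  # None = unconditional
    priority: int = 0

    def matches(self, values: Mapping[str, float]) -> bool:
        return self.antecedent is None or self.antecedent.holds(values)


@dataclass
class KnowledgeBase:
    rules: list[FuzzyRule]
    epsilon_floor: float = 0.001

    def __post_init__(self) -> None:
        if self.epsilon_floor <= 0:
            raise KnowledgeBaseError("epsilon_floor must be > 0")
        if not self.rules:
            raise KnowledgeBaseError("knowledge base has no rules")

    @property
    def target_variables(self) -> list[str]:
        seen: list[str] = []
        for r in self.rules:
            if r.target_variable not in seen:
                seen.append(r.target_variable)
        return seen

    def select_rule(self, variable: str, values: Mapping[str, float]) -> FuzzyRule:
        matching = [r for r in self.rules if r.target_variable == variable and r.matches(values)]
        if not matching:
            raise KnowledgeBaseError(f"no rule covers variable {variable!r} for these values")
        best = max(r.priority for r in matching)
        winners = [r for r in matching if r.priority == best]
        if len(winners) > 1:
            raise KnowledgeBaseError(
                f"ambiguous rules for variable {variable!r}: "
                f"{len(winners)} rules at priority {best}"
            )
        return winners[0]

    def is_unconditional(self, variable: str) -> FuzzyRule | None:
        """The single unconditional rule for ``variable``, if that is all there is."""
        rules = [r for r in self.rules if r.target_variable == variable]
        if len(rules) == 1 and rules[0].antecedent is None:
            return rules[0]
        return None

    # -- serialization --------------------------------------------------

    def to_config(self) -> dict:
        return {
            "epsilon_floor": self.epsilon_floor,
            "rules": [
                {
                    "target": r.target_variable,
                    "priority": r.priority,
                    "when": r.antecedent.to_config() if r.antecedent else None,
                    "anchors": [[float(x), float(y)] for x, y in r.transform.anchors],
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "KnowledgeBase":
        rules = []
        for rc in cfg["rules"]:
            rules.append(
                FuzzyRule(
                    target_variable=rc["target"],
                    transform=TransformFunction(tuple((x, y) for x, y in rc["anchors"])),
                    antecedent=Antecedent.parse(rc.get("when")),
                    priority=int(rc.get("priority", 0)),
                )
            )
        return cls(rules=rules, epsilon_floor=float(cfg.get("epsilon_floor", 0.001)))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "KnowledgeBase":
        return cls.from_config(yaml.safe_load(Path(path).read_text()))


def evaluate_rules(kb: KnowledgeBase, area_values: Mapping[str, float]) -> dict[str, float]:
    """Fire the knowledge base on one area's simulated values.

    For each target variable the matching rule of highest priority wins;
    the transformed value is floored at ``kb.epsilon_floor``.
    """
    out = {}
    for var in kb.target_variables:
        if var not in area_values:
            raise KnowledgeBaseError(f"area values missing variable {var!r}")
        rule = kb.select_rule(var, area_values)
        out[var] = max(kb.epsilon_floor, apply_transform(rule.transform, area_values[var]))
    return out


def transform_replicates(kb: KnowledgeBase, reps: ReplicateSet) -> ReplicateSet:
    """Apply the knowledge base to every cell of a replicate set.

    Variables governed by a single unconditional rule are transformed
    vectorised; conditional variables fall back to per-cell rule dispatch.
    Output values lie in [epsilon_floor, 1].
    """
    values = reps.values
    out = np.empty_like(values)
    col = {v: j for j, v in enumerate(reps.variables)}
    for var in reps.variables:
        if var not in kb.target_variables:
            raise KnowledgeBaseError(f"knowledge base does not cover variable {var!r}")
    slow_vars = []
    for var in reps.variables:
        rule = kb.is_unconditional(var)
        if rule is not None:
            out[:, :, col[var]] = np.maximum(kb.epsilon_floor, rule.transform(values[:, :, col[var]]))
        else:
            slow_vars.append(var)
    if slow_vars:
        R, n, _ = values.shape
        for r in range(R):
            for i in range(n):
                cell = {v: values[r, i, col[v]] for v in reps.variables}
                try:
                    for var in slow_vars:
                        rule = kb.select_rule(var, cell)
                        out[r, i, col[var]] = max(
                            kb.epsilon_floor, apply_transform(rule.transform, cell[var])
                        )
                except KnowledgeBaseError as exc:
                    raise KnowledgeBaseError(
                        f"replicate {r}, area {reps.source.areas[i].area_id!r}: {exc}"
                    ) from None
    return reps.with_values(out)


def default_knowledge_base(
    marginals: Mapping[str, MarginalSpec] | None = None,
    roles: Mapping[str, str] | None = None,
    epsilon_floor: float = 0.001,
) -> KnowledgeBase:
    """A reproducible stand-in knowledge base, one unconditional rule per variable.

    Outputs (utilisation) get a rising transform over the variable's
    observed [min, max] — higher treated prevalence or frequentation is
    always more appropriate.  Inputs (structure) get a unimodal transform
    peaking at the variable's reference mean — both scarcity and oversupply
    relative to the regional norm count as less appropriate, which encodes
    the balance idea of the care model.

    This shipped default is an editable, documented stand-in; it is not a
    validated expert rule set, and analyses of real systems should load a
    locally validated knowledge base instead.
    """
    from .dataset import default_registry

    if marginals is None:
        marginals = REFERENCE_MARGINALS
    if roles is None:
        roles = {v.name: v.role for v in default_registry()}
    rules = []
    for var, m in marginals.items():
        role = roles.get(var, "input")
        if role == "output":
            anchors = ((m.min, 0.0), (m.max, 1.0)) if m.max > m.min else ((m.min, 1.0),)
        else:
            pts = []
            if m.min < m.mean:
                pts.append((m.min, 0.0))
            pts.append((m.mean, 1.0))
            if m.max > m.mean:
                pts.append((m.max, 0.0))
            anchors = tuple(pts)
        rules.append(FuzzyRule(target_variable=var, transform=TransformFunction(anchors)))
    return KnowledgeBase(rules=rules, epsilon_floor=epsilon_floor)
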