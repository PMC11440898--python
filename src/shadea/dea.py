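"""Variable-returns-to-scale data envelopment analysis (BCC envelopment form).

Each decision-making unit (DMU; here a catchment area) is scored against
the convex hull of all observed input/output bundles.  Input orientation
solves

    min theta  s.t.  X' lam <= theta * x0,  Y' lam >= y0,  sum(lam) = 1, lam >= 0

and reports relative technical efficiency RTE = theta in (0, 1].  Output
orientation solves

    max phi    s.t.  X' lam <= x0,  Y' lam >= phi * y0,  sum(lam) = 1, lam >= 0

and reports RTE = 1/phi.  The convexity constraint sum(lam) = 1 makes
returns to scale variable.  Only the radial score is computed; the slack
maximisation second stage is omitted, so weakly efficient units may score 1.

A brute-force simplex-grid oracle is included for small instances; it is
used in the test suite as an LP-independent check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "DEAInstance",
    "DEAResult",
    "DEAError",
    "solve_input_oriented",
    "solve_output_oriented",
    "solve_all",
    "rte_scores",
    "brute_force_oracle",
]

EFFICIENT_TOL = 1e-6


class DEAError(RuntimeError):
    """LP failure or invalid instance."""


@dataclass
class DEAInstance:
    """One comparison set: n DMUs with strictly positive inputs X (n x m_in)
    and nonnegative outputs Y (n x m_out, each DMU with >= 1 positive output)."""

    dmu_ids: list[str]
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = len(self.dmu_ids)
        if self.X.ndim != 2 or self.Y.ndim != 2 or self.X.shape[0] != n or self.Y.shape[0] != n:
            raise DEAError("X and Y must be 2-D with one row per DMU")
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise DEAError("NaN in DEA instance")
        if (self.X <= 0).any():
            raise DEAError("inputs must be strictly positive (apply the epsilon floor upstream)")
        if (self.Y < 0).any() or (self.Y.max(axis=1) <= 0).any():
            raise DEAError("outputs must be nonnegative with at least one positive output per DMU")

    @property
    def n(self) -> int:
        return len(self.dmu_ids)

    def index(self, dmu_id: str) -> int:
        try:
            return self.dmu_ids.index(dmu_id)
        except ValueError:
            raise DEAError(f"unknown DMU {dmu_id!r}") from None


@dataclass
class DEAResult:
    dmu_id: str
    orientation: str
    theta: float  # radial factor: theta in (0,1] (input) or phi >= 1 (output)
    rte: float
    lambdas: np.ndarray
    efficient: bool


def _solve(inst: DEAInstance, k: int, orientation: str) -> tuple[float, np.ndarray]:
    n = inst.n
    m_in = inst.X.shape[1]
    m_out = inst.Y.shape[1]
    # variables: lam_1..lam_n, t (theta or phi)
    c = np.zeros(n + 1)
    c[-1] = 1.0 if orientation == "input" else -1.0
    A_ub = np.zeros((m_in + m_out, n + 1))
    b_ub = np.zeros(m_in + m_out)
    A_ub[:m_in, :n] = inst.X.T
    A_ub[m_in:, :n] = -inst.Y.T
    if orientation == "input":
        A_ub[:m_in, -1] = -inst.X[k]
        b_ub[m_in:] = -inst.Y[k]
    elif orientation == "output":
        b_ub[:m_in] = inst.X[k]
        A_ub[m_in:, -1] = inst.Y[k]
    else:
        raise DEAError(f"orientation must be 'input' or 'output', got {orientation!r}")
    A_eq = np.zeros((1, n + 1))
    A_eq[0, :n] = 1.0
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=[(0.0, None)] * n + [(None, None)],
        method="highs",
    )
    if not res.success:
        raise DEAError(f"LP failed for DMU {inst.dmu_ids[k]!r} ({orientation}): {res.message}")
    return float(res.x[-1]), res.x[:n]


def _result(inst: DEAInstance, k: int, orientation: str, tol: float) -> DEAResult:
    t, lam = _solve(inst, k, orientation)
    rte = t if orientation == "input" else 1.0 / t
    rte = float(np.clip(rte, 0.0, 1.0))
    return DEAResult(
        dmu_id=inst.dmu_ids[k],
        orientation=orientation,
        theta=t,
        rte=rte,
        lambdas=lam,
        efficient=rte >= 1.0 - tol,
    )


def solve_input_oriented(inst: DEAInstance, dmu_id: str, tol: float = EFFICIENT_TOL) -> DEAResult:
    """Radial input contraction: how far can x0 shrink inside the hull."""
    return _result(inst, inst.index(dmu_id), "input", tol)


def solve_output_oriented(inst: DEAInstance, dmu_id: str, tol: float = EFFICIENT_TOL) -> DEAResult:
    """Radial output expansion: how far can y0 grow inside the hull."""
    return _result(inst, inst.index(dmu_id), "output", tol)


def solve_all(inst: DEAInstance, orientation: str, tol: float = EFFICIENT_TOL) -> list[DEAResult]:
    """Score every DMU; results are independent of DMU ordering."""
    return [_result(inst, k, orientation, tol) for k in range(inst.n)]


def rte_scores(X: np.ndarray, Y: np.ndarray, orientation: str) -> np.ndarray:
    """RTE vector for matrices already validated upstream (pipeline fast path)."""
    inst = DEAInstance(dmu_ids=[str(i) for i in range(len(X))], X=X, Y=Y)
    return np.array([r.rte for r in solve_all(inst, orientation)])


def _simplex_grid(n: int, steps: int) -> np.ndarray:
    """All lambda vectors with components j/steps summing to 1 (stars & bars)."""
    combos = np.array(
        list(itertools.combinations(range(steps + n - 1), n - 1)), dtype=np.int64
    ).reshape(-1, n - 1)
    bounded = np.hstack(
        [
            np.full((len(combos), 1), -1, dtype=np.int64),
            combos,
            np.full((len(combos), 1), steps + n - 1, dtype=np.int64),
        ]
    )
    return np.diff(bounded, axis=1) - 1


def brute_force_oracle(
    inst: DEAInstance, dmu_id: str, orientation: str, grid: float = 1e-2
) -> float:
    """Approximate RTE by enumerating lambda on a simplex grid.

    Deliberately independent of the LP path; restricted to tiny instances
    (<= 6 DMUs, <= 3 inputs, <= 2 outputs).  The LP answer must agree
    within O(grid).
    """
    if inst.n > 6 or inst.X.shape[1] > 3 or inst.Y.shape[1] > 2:
        raise DEAError("oracle restricted to <= 6 DMUs, <= 3 inputs, <= 2 outputs")
    k = inst.index(dmu_id)
    steps = int(round(1.0 / grid))
    lam = _simplex_grid(inst.n, steps) / steps
    vx = lam @ inst.X  # (M, m_in) virtual inputs
    vy = lam @ inst.Y  # (M, m_out) virtual outputs
    if orientation == "input":
        feasible = (vy >= inst.Y[k] - 1e-12).all(axis=1)
        if not feasible.any():
            return 1.0
        theta = (vx[feasible] / inst.X[k]).max(axis=1)
        return float(min(theta.min(), 1.0))
    if orientation == "output":
        feasible = (vx <= inst.X[k] + 1e-12).all(axis=1)
        if not feasible.any():
            return 1.0
        yk = np.where(inst.Y[k] > 0, inst.Y[k], np.inf)
        phi = (vy[feasible] / yk).min(axis=1)
        return float(1.0 / max(phi.max(), 1.0))
    raise DEAError(f"orientation must be 'input' or 'output', got {orientation!r}")
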