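"""Welfare-maximising allocation of a public budget across departments.

Each department j turns its budget share m_j into a health outcome h_j(m_j)
and a non-health outcome a_j(m_j), both expressed in monetary benefit. With
upsilon the social exchange rate between the health and non-health
attributes, total welfare is the utilitarian sum

    W = upsilon * sum_j h_j(m_j) + sum_j a_j(m_j),   sum_j m_j = M, m_j >= 0.

At an interior optimum the combined marginal welfare
g_j(m) = upsilon * h_j'(m) + a_j'(m) is equalised across departments, which
is equivalent to the pairwise condition

    upsilon * (h_i' - h_j') = a_j' - a_i'   for every pair (i, j).

Production functions must be non-decreasing and concave on [0, M]; the
default parametric form is the power function c * m**beta with 0 < beta < 1.
The solver is a monotone scalar search on the common marginal value, with
departments whose marginal welfare never reaches it parked at zero
(active-set treatment of the non-negativity constraints).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PowerProduction",
    "TabulatedProjects",
    "Department",
    "AllocationProblem",
    "AllocationSolution",
    "solve_allocation",
    "check_equilibrium",
    "threshold_gap_demo",
]


@dataclass(frozen=True)
class PowerProduction:
    """Concave power-form production c * m**beta (0 < beta < 1), in money units.

    ``scale`` may be zero for an unproductive attribute.
    """

    scale: float
    beta: float

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if not (0 < self.beta < 1):
            raise ValueError("beta must lie in (0, 1) for strict concavity")

    def __call__(self, m: float) -> float:
        return self.scale * m**self.beta

    def marginal(self, m: float) -> float:
        if self.scale == 0:
            return 0.0
        if m <= 0:
            return np.inf
        return self.scale * self.beta * m ** (self.beta - 1.0)


@dataclass(frozen=True)
class Department:
    name: str
    health: Callable[[float], float]          # h_j, monetary health benefit
    amenity: Callable[[float], float]         # a_j, monetary non-health benefit

    def _marginal(self, fn: Callable[[float], float], m: float, step: float) -> float:
        g = getattr(fn, "marginal", None)
        if g is not None:
            return g(m)
        lo = max(m - step, 0.0)
        return (fn(m + step) - fn(lo)) / (m + step - lo)

    def marginal_health(self, m: float, step: float = 1e-6) -> float:
        return self._marginal(self.health, m, step)

    def marginal_amenity(self, m: float, step: float = 1e-6) -> float:
        return self._marginal(self.amenity, m, step)


@dataclass(frozen=True)
class AllocationProblem:
    budget: float                      # M
    departments: Sequence[Department]  # J >= 2
    upsilon: float                     # social value of health vs non-health

    def __post_init__(self) -> None:
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        if len(self.departments) < 2:
            raise ValueError("need at least two departments")
        if self.upsilon < 0:
            raise ValueError("upsilon must be non-negative")

    def marginal_welfare(self, j: int, m: float) -> float:
        d = self.departments[j]
        step = 1e-6 * self.budget
        return self.upsilon * d.marginal_health(m, step) + d.marginal_amenity(m, step)

    def welfare(self, m: Sequence[float]) -> float:
        return sum(
            self.upsilon * d.health(x) + d.amenity(x)
            for d, x in zip(self.departments, m)
        )


@dataclass
class AllocationSolution:
    allocations: np.ndarray
    marginal_health: np.ndarray
    marginal_amenity: np.ndarray
    welfare: float
    max_residual: float                # worst pairwise equilibrium residual
    multiplier: float                  # common marginal welfare at the optimum
    residuals: np.ndarray = field(repr=False)  # J x J pairwise matrix


def _probe_concavity(problem: AllocationProblem, n_probe: int = 24) -> None:
    """Reject inputs whose marginal welfare increases along [0, M]."""
    ms = np.linspace(problem.budget * 1e-6, problem.budget, n_probe)
    for j in range(len(problem.departments)):
        g = [problem.marginal_welfare(j, m) for m in ms]
        diffs = np.diff(g)
        tol = 1e-9 * (abs(g[0]) + abs(g[-1]) + 1.0)
        if np.any(diffs > tol):
            raise ValueError(
                f"department {problem.departments[j].name!r}: marginal welfare "
                "increases with budget; production functions must be concave"
            )


def solve_allocation(
    problem: AllocationProblem, tolerance: float = 1e-9
) -> AllocationSolution:
    """Maximise welfare subject to the budget constraint.

    The optimum equalises g_j = upsilon*h_j' + a_j' across departments with
    interior allocations; departments whose marginal welfare at zero falls
    short of the common value receive nothing.
    """
    _probe_concavity(problem)
    J = len(problem.departments)
    M = problem.budget
    eps = M * 1e-12

    def m_of_lambda(j: int, lam: float) -> float:
        g_hi = problem.marginal_welfare(j, eps)
        if g_hi <= lam:
            return 0.0
        g_lo = problem.marginal_welfare(j, M)
        if g_lo >= lam:
            return M
        return brentq(lambda m: problem.marginal_welfare(j, m) - lam, eps, M,
                      xtol=eps, rtol=8.8817841970012523e-16)

    def spent(lam: float) -> float:
        return sum(m_of_lambda(j, lam) for j in range(J))

    lam_lo = min(problem.marginal_welfare(j, M) for j in range(J))
    if spent(max(lam_lo, 0.0)) < M:
        # every department saturated below M only if marginals hit zero; then
        # any completion is optimal - allocate the remainder uniformly
        m = np.array([m_of_lambda(j, max(lam_lo, 0.0)) for j in range(J)])
        m += (M - m.sum()) / J
        lam = max(lam_lo, 0.0)
    else:
        lam_hi = max(max(problem.marginal_welfare(j, eps) for j in range(J)), lam_lo)
        if not np.isfinite(lam_hi):
            lam_hi = max(1.0, abs(lam_lo)) * 2.0
            while spent(lam_hi) > M:
                lam_hi *= 4.0
        lam = brentq(lambda L: spent(L) - M, lam_lo, lam_hi,
                     xtol=tolerance, rtol=8.8817841970012523e-16)
        m = np.array([m_of_lambda(j, lam) for j in range(J)])
        m *= M / m.sum()  # absorb the last float ulp into the constraint

    step = 1e-6 * M
    mh = np.array([d.marginal_health(x, step) for d, x in zip(problem.departments, m)])
    ma = np.array([d.marginal_amenity(x, step) for d, x in zip(problem.departments, m)])
    resid = _pairwise_residuals(problem, m)
    interior = m > eps
    max_res = float(np.abs(resid[np.ix_(interior, interior)]).max()) if interior.sum() >= 2 else 0.0
    return AllocationSolution(
        allocations=m,
        marginal_health=mh,
        marginal_amenity=ma,
        welfare=problem.welfare(m),
        max_residual=max_res,
        multiplier=float(lam),
        residuals=resid,
    )


def _pairwise_residuals(problem: AllocationProblem, m: Sequence[float]) -> np.ndarray:
    """Residuals of upsilon*(h_i' - h_j') - (a_j' - a_i') for every pair."""
    step = 1e-6 * problem.budget
    mh = [d.marginal_health(x, step) for d, x in zip(problem.departments, m)]
    ma = [d.marginal_amenity(x, step) for d, x in zip(problem.departments, m)]
    J = len(mh)
    res = np.zeros((J, J))
    for i in range(J):
        for j in range(J):
            res[i, j] = problem.upsilon * (mh[i] - mh[j]) - (ma[j] - ma[i])
    return res


@dataclass
class EquilibriumReport:
    residuals: np.ndarray
    max_residual: float

    def __str__(self) -> str:
        return f"max |pairwise residual| = {self.max_residual:.3e}"


def check_equilibrium(
    problem: AllocationProblem, allocation: Sequence[float]
) -> EquilibriumReport:
    """Evaluate the pairwise optimality condition at a candidate allocation.

    Marginals use exact derivatives where the production form provides them,
    central finite differences (step 1e-6 * M) otherwise. The allocation must
    exhaust the budget.
    """
    m = np.asarray(allocation, dtype=float)
    if not np.isclose(m.sum(), problem.budget, rtol=1e-9):
        raise ValueError(f"allocation sums to {m.sum()}, budget is {problem.budget}")
    res = _pairwise_residuals(problem, m)
    return EquilibriumReport(res, float(np.abs(res).max()))


@dataclass(frozen=True)
class TabulatedProjects:
    """Candidate projects for the threshold-gap demonstration."""

    costs: np.ndarray       # implementation cost of each project
    qalys: np.ndarray       # QALYs each project would generate

    @classmethod
    def synthetic(cls, n: int, low_threshold: float, high_threshold: float,
                  seed: int = 0) -> "TabulatedProjects":
        """Projects whose cost-per-QALY spans and straddles both thresholds."""
        rng = np.random.default_rng(seed)
        qalys = rng.uniform(10.0, 500.0, n)
        cost_per_qaly = rng.uniform(0.5 * low_threshold, 1.5 * high_threshold, n)
        return cls(costs=qalys * cost_per_qaly, qalys=qalys)


@dataclass
class ThresholdGapReport:
    inconsistent: list[tuple[int, str, str]]  # (project, accepting dept, rejecting dept)
    accepted: dict[str, list[int]]
    welfare_loss: float
    reference_voq: float


def threshold_gap_demo(
    department_thresholds: dict[str, float],
    projects: TabulatedProjects,
    reference_voq: Optional[float] = None,
) -> ThresholdGapReport:
    """Show how divergent per-QALY thresholds misallocate across departments.

    Each department accepts a project iff QALYs * threshold >= cost. A project
    accepted under one department's rule but rejected under another's is
    inconsistently valued: its fate depends on which department happens to
    appraise it. Welfare is scored against a single reference value of a QALY
    (default: the mean threshold); the loss is the net benefit forgone
    relative to accepting exactly the projects with non-negative net benefit
    at that reference value. The loss is zero when all thresholds equal the
    reference and non-negative always.
    """
    if any(t <= 0 for t in department_thresholds.values()):
        raise ValueError("thresholds must be positive")
    if reference_voq is None:
        reference_voq = float(np.mean(list(department_thresholds.values())))
    names = list(department_thresholds)
    accept = {
        d: projects.qalys * department_thresholds[d] >= projects.costs for d in names
    }
    inconsistent = []
    for k in range(len(projects.costs)):
        for i in names:
            for j in names:
                if accept[i][k] and not accept[j][k]:
                    inconsistent.append((k, i, j))
    net = projects.qalys * reference_voq - projects.costs
    best = float(net[net >= 0].sum())
    # each department appraises its own copy of the slate; realised welfare is
    # the average over departments of the net benefit of what that rule accepts
    realised = float(np.mean([net[accept[d]].sum() for d in names]))
    return ThresholdGapReport(
        inconsistent=inconsistent,
        accepted={d: list(np.flatnonzero(accept[d])) for d in names},
        welfare_loss=best - realised,
        reference_voq=reference_voq,
    )
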