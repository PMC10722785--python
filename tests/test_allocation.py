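"""Welfare-optimal budget allocation: solver, equilibrium condition, demos."""

import numpy as np
import pytest

from lifevalues import (AllocationProblem, Department, PowerProduction,
                        TabulatedProjects, check_equilibrium, solve_allocation,
                        threshold_gap_demo)


def power_problem(c, d, beta, upsilon=1.0, budget=1e7):
    departments = [
        Department(f"d{j}", PowerProduction(cj, beta), PowerProduction(dj, beta))
        for j, (cj, dj) in enumerate(zip(c, d))
    ]
    return AllocationProblem(budget=budget, departments=departments, upsilon=upsilon)


def closed_form_optimum(c, d, beta, upsilon, budget):
    """Lagrange solution for shared-exponent power forms."""
    w = (upsilon * np.asarray(c) + np.asarray(d)) ** (1.0 / (1.0 - beta))
    return budget * w / w.sum()


def grid_search(problem, steps=1000):
    """Brute-force oracle: exhaustive search on an M/steps lattice (J<=3)."""
    M, J = problem.budget, len(problem.departments)
    ticks = np.linspace(0.0, M, steps + 1)
    best, best_w = None, -np.inf
    if J == 2:
        for m0 in ticks:
            w = problem.welfare([m0, M - m0])
            if w > best_w:
                best, best_w = [m0, M - m0], w
    elif J == 3:
        for m0 in ticks[::10]:
            for m1 in np.linspace(0.0, M - m0, 101):
                w = problem.welfare([m0, m1, M - m0 - m1])
                if w > best_w:
                    best, best_w = [m0, m1, M - m0 - m1], w
    else:
        raise ValueError("grid oracle supports J<=3")
    return np.array(best), best_w


class TestSolver:
    def test_identical_departments_split_equally(self):
        p = power_problem([2.0, 2.0], [1.0, 1.0], beta=0.5)
        sol = solve_allocation(p)
        assert sol.allocations == pytest.approx([p.budget / 2] * 2, rel=1e-9)

    @pytest.mark.parametrize("c, d, beta, upsilon", [
        ([2.0, 1.0], [1.0, 3.0], 0.5, 1.5),
        ([1.0, 4.0, 2.0], [3.0, 1.0, 2.0], 0.3, 0.7),
        ([5.0, 0.5], [0.5, 5.0], 0.7, 2.0),
    ])
    def test_matches_closed_form(self, c, d, beta, upsilon):
        p = power_problem(c, d, beta, upsilon)
        sol = solve_allocation(p)
        expected = closed_form_optimum(c, d, beta, upsilon, p.budget)
        assert np.max(np.abs(sol.allocations - expected) / expected) < 1e-6

    def test_matches_grid_search_oracle(self):
        p = power_problem([2.0, 1.0], [1.0, 3.0], beta=0.5, upsilon=1.5)
        sol = solve_allocation(p)
        m_grid, w_grid = grid_search(p)
        assert np.max(np.abs(sol.allocations - m_grid)) <= p.budget / 1000
        assert sol.welfare >= w_grid - 1e-9

    def test_three_department_grid_search(self):
        p = power_problem([1.0, 4.0, 2.0], [3.0, 1.0, 2.0], beta=0.3, upsilon=0.7)
        sol = solve_allocation(p)
        m_grid, _ = grid_search(p)
        assert np.max(np.abs(sol.allocations - m_grid)) <= p.budget / 50

    def test_zero_upsilon_ignores_health_production(self):
        # amenity productivities equal, health wildly different: equal split
        p = power_problem([100.0, 0.01], [2.0, 2.0], beta=0.5, upsilon=0.0)
        sol = solve_allocation(p)
        assert sol.allocations == pytest.approx([p.budget / 2] * 2, rel=1e-9)

    def test_unproductive_department_gets_nothing(self):
        base = power_problem([2.0, 1.0], [1.0, 3.0], beta=0.5, upsilon=1.5)
        with_dud = AllocationProblem(
            budget=base.budget,
            departments=list(base.departments) + [
                Department("dud", PowerProduction(0.0, 0.5), PowerProduction(0.0, 0.5))],
            upsilon=base.upsilon,
        )
        sol_base = solve_allocation(base)
        sol = solve_allocation(with_dud)
        assert sol.allocations[-1] == pytest.approx(0.0, abs=base.budget * 1e-9)
        assert sol.allocations[:2] == pytest.approx(sol_base.allocations, rel=1e-7)

    def test_scale_invariance_of_power_forms(self):
        p1 = power_problem([2.0, 1.0], [1.0, 3.0], beta=0.5, budget=1e6)
        p2 = power_problem([2.0, 1.0], [1.0, 3.0], beta=0.5, budget=1e9)
        s1, s2 = solve_allocation(p1), solve_allocation(p2)
        assert s2.allocations / s1.allocations == pytest.approx([1e3, 1e3], rel=1e-7)

    def test_budget_constraint_and_nonnegativity(self):
        p = power_problem([1.0, 4.0, 2.0], [3.0, 1.0, 2.0], beta=0.3, upsilon=0.7)
        sol = solve_allocation(p)
        assert sol.allocations.sum() == pytest.approx(p.budget, rel=1e-12)
        assert (sol.allocations >= 0).all()

    def test_nonconcave_production_rejected(self):
        class Convex:
            def __call__(self, m):
                return m**2

            def marginal(self, m):
                return 2 * m

        p = AllocationProblem(
            budget=100.0,
            departments=[
                Department("bad", Convex(), PowerProduction(1.0, 0.5)),
                Department("ok", PowerProduction(1.0, 0.5), PowerProduction(1.0, 0.5)),
            ],
            upsilon=1.0,
        )
        with pytest.raises(ValueError, match="concave"):
            solve_allocation(p)

    def test_invalid_problems_rejected(self):
        with pytest.raises(ValueError):
            power_problem([1.0, 1.0], [1.0, 1.0], 0.5, budget=-5)
        with pytest.raises(ValueError):
            AllocationProblem(budget=1.0, departments=[
                Department("only", PowerProduction(1, 0.5), PowerProduction(1, 0.5))],
                upsilon=1.0)


class TestEquilibrium:
    def test_residual_small_at_reported_optimum(self):
        p = power_problem([2.0, 1.0], [1.0, 3.0], beta=0.5, upsilon=1.5)
        sol = solve_allocation(p)
        report = check_equilibrium(p, sol.allocations)
        scale = abs(sol.multiplier)
        assert report.max_residual <= 1e-6 * scale

    def test_residual_grows_with_perturbation(self):
        p = power_problem([2.0, 1.0], [1.0, 3.0], beta=0.5, upsilon=1.5)
        sol = solve_allocation(p)
        resids = []
        for frac in (0.0, 0.05, 0.1, 0.2):
            shift = frac * p.budget / 2
            m = [sol.allocations[0] + shift, sol.allocations[1] - shift]
            resids.append(check_equilibrium(p, m).max_residual)
        assert resids == sorted(resids)

    def test_budget_mismatch_rejected(self):
        p = power_problem([2.0, 1.0], [1.0, 3.0], beta=0.5)
        with pytest.raises(ValueError, match="budget"):
            check_equilibrium(p, [1.0, 2.0])

    def test_allocation_shifts_away_from_health_as_upsilon_falls(self):
        """Health-productive department loses budget as society discounts health."""
        shares = []
        for upsilon in (2.0, 1.5, 1.0, 0.5, 0.1):
            p = power_problem([3.0, 0.5], [0.5, 3.0], beta=0.5, upsilon=upsilon)
            shares.append(solve_allocation(p).allocations[0])
        assert shares == sorted(shares, reverse=True)


class TestThresholdGap:
    def test_identical_thresholds_are_consistent(self):
        projects = TabulatedProjects.synthetic(40, 30000, 30000, seed=1)
        rep = threshold_gap_demo({"health": 30000.0, "transport": 30000.0}, projects)
        assert rep.inconsistent == []
        assert rep.welfare_loss == pytest.approx(0.0, abs=1e-9)

    def test_divergent_uk_style_thresholds_disagree(self):
        """Projects priced between the health and transport VOQ thresholds are
        accepted by one department's rule and rejected by the other's."""
        projects = TabulatedProjects.synthetic(60, 30000, 73535, seed=1)
        rep = threshold_gap_demo({"health": 30000.0, "transport": 73535.0}, projects)
        assert rep.inconsistent
        accepted_t = set(rep.accepted["transport"])
        accepted_h = set(rep.accepted["health"])
        assert accepted_h <= accepted_t  # the lower threshold is stricter

    @pytest.mark.parametrize("seed", [0, 7, 23])
    def test_welfare_loss_nonnegative(self, seed):
        projects = TabulatedProjects.synthetic(50, 20000, 80000, seed=seed)
        rep = threshold_gap_demo({"a": 20000.0, "b": 50000.0, "c": 80000.0}, projects)
        assert rep.welfare_loss >= 0

    def test_nonpositive_threshold_rejected(self):
        projects = TabulatedProjects.synthetic(5, 1000, 2000, seed=0)
        with pytest.raises(ValueError):
            threshold_gap_demo({"a": -1.0}, projects)
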