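"""Tests for the survey/removal MILP, its variants and the oracles."""

import dataclasses

import numpy as np
import pytest

from pestsurvey.landscape import ScenarioSet
from pestsurvey.optimize import (
    MenuOption,
    NONE_OPTION,
    ProblemData,
    SamplingMenu,
    brute_force_oracle,
    build_cvar,
    build_survey_only_p1,
    build_survey_only_p2,
    build_survey_removal,
    cvar_of,
    default_menu,
    evaluate_plan,
    solve,
    split_budget,
    two_stage_removal,
    write_lp,
)
from pestsurvey.costs import RemovalCostSpec

from conftest import line_landscape, tiny_problem


def _none_only_problem(J=2, S=3, seed=0):
    rng = np.random.default_rng(seed)
    land = line_landscape(J, rng=rng)
    gamma = rng.uniform(0.1, 0.5, size=(S, J))
    menu = SamplingMenu(options=[[NONE_OPTION] for _ in range(J)])
    return ProblemData(
        landscape=land,
        scenarios=ScenarioSet(gamma=gamma),
        menu=menu,
        budget_total=100.0,
    )


class TestModelStructure:
    def test_constraint_labels(self):
        data = tiny_problem(seed=1, J=3, S=4)
        model = build_survey_removal(data)
        budget_rows = [l for l in model.labels_ub if l.startswith("budget-19")]
        assert len(budget_rows) == 4  # one per scenario
        one_opt = [l for l in model.labels_eq if l.startswith("one-option-20")]
        assert len(one_opt) == 3  # one per site

    def test_menu_option_exceeding_hosts_rejected(self):
        land = line_landscape(1, hosts=np.array([3]))
        menu = SamplingMenu(
            options=[[NONE_OPTION, MenuOption("trap", 5, 10.0, 0.5)]]
        )
        with pytest.raises(ValueError):
            ProblemData(
                landscape=land,
                scenarios=ScenarioSet(gamma=np.array([[0.2]])),
                menu=menu,
                budget_total=100.0,
            )

    def test_menu_requires_exactly_one_none(self):
        with pytest.raises(ValueError):
            SamplingMenu(options=[[NONE_OPTION, NONE_OPTION]])
        with pytest.raises(ValueError):
            SamplingMenu(options=[[MenuOption("trap", 1, 1.0, 0.5)]])

    def test_default_menu_caps_levels_at_hosts(self):
        land = line_landscape(2, hosts=np.array([3, 200]))
        menu = default_menu(land)
        ns0 = sorted(o.n for o in menu.options[0] if o.method == "trap")
        assert ns0 == [1, 2]
        ns1 = sorted(o.n for o in menu.options[1] if o.method == "trap")
        assert ns1 == [1, 2, 5, 10, 25, 50, 100]

    def test_lp_export(self, tmp_path):
        model = build_survey_removal(tiny_problem(seed=2))
        path = tmp_path / "model.lp"
        write_lp(model, path)
        text = path.read_text()
        assert text.startswith("Minimize")
        assert "Binaries" in text and "End" in text


class TestTrivialOptima:
    def test_none_only_menu_gives_full_expectation(self):
        data = _none_only_problem()
        sol = solve(build_survey_removal(data))
        expected = (data.scenarios.gamma * data.landscape.hosts).sum(axis=1).mean()
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(expected, rel=1e-9)

    def test_budget_below_cheapest_survey_forces_none(self):
        data = tiny_problem(seed=3, budget=0.5)
        sol = solve(build_survey_removal(data))
        assert all(m is None for m, _ in sol.chosen)

    def test_zero_infestation_gives_zero_objective(self):
        data = tiny_problem(seed=4)
        data = dataclasses.replace(
            data, scenarios=ScenarioSet(gamma=np.zeros_like(data.scenarios.gamma))
        )
        sol = solve(build_survey_removal(data))
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_split_budget_reported(self):
        data = tiny_problem(seed=5, budget=600.0)
        # a survey cap below zero spending is impossible to violate, but a
        # negative cap is impossible to satisfy together with sum(x)=1 rows
        # only when every option costs money; use total below the none plan
        model = build_survey_removal(data)
        model.b_ub[model.labels_ub.index("budget-19[s=0]")] = -1.0
        sol = solve(model)
        assert sol.status == "infeasible"


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_joint_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        data = tiny_problem(
            seed=seed,
            J=int(rng.integers(1, 4)),
            S=int(rng.integers(1, 6)),
            budget=float(rng.uniform(50, 800)),
            removal_cost=float(rng.uniform(10, 120)),
        )
        sol = solve(build_survey_removal(data), mip_rel_gap=1e-9)
        orc = brute_force_oracle(data)
        assert sol.objective == pytest.approx(orc.objective, rel=1e-5, abs=1e-7)

    @pytest.mark.parametrize("problem", ["p1", "p2"])
    def test_survey_only_matches_enumeration(self, problem):
        data = tiny_problem(seed=11, J=3, S=4, budget=120.0)
        builder = build_survey_only_p1 if problem == "p1" else build_survey_only_p2
        sol = solve(builder(data), mip_rel_gap=1e-9)
        orc = brute_force_oracle(data, problem=problem)
        assert sol.objective == pytest.approx(orc.objective, rel=1e-6)

    def test_grid_and_lp_inner_oracles_agree(self):
        """The 0.01-step grid search over removal fractions and the inner
        LP reach the same optimum up to the grid resolution (on a budget
        where at most one site can be surveyed, keeping the grid exact)."""
        land = line_landscape(2, hosts=np.array([20, 15]))
        menu = SamplingMenu(
            options=[
                [NONE_OPTION, MenuOption("trap", 4, 5.0, 0.5)],
                [NONE_OPTION, MenuOption("branch", 3, 5.0, 0.7)],
            ]
        )
        rng = np.random.default_rng(12)
        data = ProblemData(
            landscape=land,
            scenarios=ScenarioSet(gamma=rng.uniform(0.1, 0.5, size=(3, 2))),
            menu=menu,
            removal_cost=RemovalCostSpec(unit_cost=40.0),
            budget_total=30.0,  # surveying both sites would cost 35
        )
        lp = brute_force_oracle(data, y_method="lp")
        grid = brute_force_oracle(data, y_method="grid")
        # the grid optimum cannot beat the LP, and lies within one grid
        # step of it along each removal fraction
        assert grid.objective >= lp.objective - 1e-9
        # gradient wrt each y is bounded by the site's expected infested
        # count, so two grid steps bound the resolution error
        slack = 0.02 * float(
            (data.scenarios.gamma * land.hosts).sum(axis=1).max()
        )
        assert grid.objective - lp.objective <= slack

    def test_p1_zero_gamma_objective_counts_all_sites(self):
        data = tiny_problem(seed=13, J=3, S=2, budget=1e6)
        data = dataclasses.replace(
            data, scenarios=ScenarioSet(gamma=np.zeros_like(data.scenarios.gamma))
        )
        sol = solve(build_survey_only_p1(data))
        # nothing to detect: every site contributes P = 1 whatever x is
        assert sol.objective == pytest.approx(3.0, abs=1e-9)

    def test_p1_perfect_detection_site_contributes_zero(self):
        land = line_landscape(1, hosts=np.array([5]))
        menu = SamplingMenu(
            options=[[NONE_OPTION, MenuOption("branch", 1, 1.0, 1.0)]]
        )
        data = ProblemData(
            landscape=land,
            scenarios=ScenarioSet(gamma=np.array([[1.0]])),
            menu=menu,
            budget_total=10.0,
        )
        sol = solve(build_survey_only_p1(data))
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_p2_all_none_is_total_expectation(self):
        data = _none_only_problem(J=3, S=4, seed=6)
        sol = solve(build_survey_only_p2(data))
        expected = (data.scenarios.gamma * data.landscape.hosts).sum(axis=1).mean()
        assert sol.objective == pytest.approx(expected, rel=1e-9)


class TestSolutionInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_budget_feasibility_every_scenario(self, seed):
        data = tiny_problem(seed=seed, J=4, S=5, budget=400.0)
        sol = solve(build_survey_removal(data))
        total = sol.survey_spend + sol.removal_spend
        assert np.all(total <= data.budget_total + 1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_removal_zero_without_survey(self, seed):
        data = tiny_problem(seed=seed, J=4, S=3, budget=200.0)
        sol = solve(build_survey_removal(data))
        for j, (method, _) in enumerate(sol.chosen):
            if method is None:
                assert sol.y1[j] == 0.0 and sol.y2[j] == 0.0

    def test_objective_nonincreasing_in_budget(self):
        data = tiny_problem(seed=21, J=4, S=4, removal_cost=60.0)
        objs = []
        for B in (100.0, 200.0, 400.0, 800.0):
            d = dataclasses.replace(data, budget_total=B)
            objs.append(solve(build_survey_removal(d), mip_rel_gap=1e-9).objective)
        assert all(a >= b - 1e-7 for a, b in zip(objs, objs[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_independent_objective_reevaluation(self, seed):
        """Recomputing the objective site-by-site from the slippage
        calculus reproduces the solver's objective."""
        data = tiny_problem(seed=seed, J=3, S=4, budget=500.0)
        sol = solve(build_survey_removal(data), mip_rel_gap=1e-9)
        z = evaluate_plan(data, sol)
        assert z.mean() == pytest.approx(sol.objective, abs=1e-5)
        assert np.allclose(z, sol.z_s, atol=1e-6)

    def test_rearranged_objective_equals_slippage_plus_residual(self):
        """For random feasible (x, y) the model's objective row equals the
        sum over sites of expected slippage plus post-removal residual."""
        rng = np.random.default_rng(7)
        data = tiny_problem(seed=7, J=3, S=5, budget=1e9)
        model = build_survey_removal(data)
        t = model.tables
        for _ in range(20):
            v = np.zeros(model.n_var)
            chosen = []
            y1 = np.zeros(3)
            y2 = np.zeros(3)
            for j in range(3):
                ks = np.flatnonzero(t.j_idx == j)
                k = rng.choice(ks)
                v[k] = 1.0
                o = data.menu.options[j][t.local[k]]
                chosen.append((o.method, o.n))
                if t.y_of[k] >= 0:
                    y1[j] = rng.uniform()
                    y2[j] = rng.uniform()
                    v[model.n_x + t.y_of[k]] = y1[j]
                    v[model.n_x + t.K1 + t.y_of[k]] = y2[j]
            z_model = model.scenario_obj @ v
            fake = solve(build_survey_removal(data))  # template for dataclass
            sol = dataclasses.replace(
                fake, chosen=chosen, y1=y1, y2=y2
            )
            z_direct = evaluate_plan(data, sol)
            assert np.allclose(z_model, z_direct, atol=1e-9)


class TestTwoStage:
    def test_frozen_joint_optimum_reproduces_objective(self):
        data = tiny_problem(seed=31, J=3, S=3, budget=500.0)
        joint = solve(build_survey_removal(data), mip_rel_gap=1e-9)
        staged = two_stage_removal(data, joint, mip_rel_gap=1e-9)
        assert staged.objective == pytest.approx(joint.objective, rel=1e-6)

    def test_no_leftover_budget_means_no_removal(self):
        data = tiny_problem(seed=32, J=2, S=2, budget=200.0)
        p2 = solve(build_survey_only_p2(data), mip_rel_gap=1e-9)
        # shrink the budget to exactly the survey spend: nothing left to remove
        d2 = dataclasses.replace(data, budget_total=max(p2.survey_spend, 1e-9))
        staged = two_stage_removal(d2, p2, mip_rel_gap=1e-9)
        assert np.all(staged.y1 == 0.0) and np.all(staged.y2 == 0.0)
        assert staged.objective == pytest.approx(
            evaluate_plan(d2, staged).mean(), abs=1e-6
        )

    @pytest.mark.parametrize("builder", [build_survey_only_p1, build_survey_only_p2])
    def test_joint_dominates_staged_survey_only(self, builder):
        data = tiny_problem(seed=33, J=4, S=5, budget=600.0)
        joint = solve(build_survey_removal(data), mip_rel_gap=1e-9)
        d_survey = dataclasses.replace(
            data, budget_total=max(joint.survey_spend, 1e-9)
        )
        fixed = solve(builder(d_survey), mip_rel_gap=1e-9)
        staged = two_stage_removal(data, fixed, mip_rel_gap=1e-9)
        assert joint.objective <= staged.objective + 1e-6

    def test_overspending_fixed_plan_rejected(self):
        data = tiny_problem(seed=34, J=3, S=2, budget=1000.0)
        joint = solve(build_survey_removal(data), mip_rel_gap=1e-9)
        d_small = dataclasses.replace(data, budget_total=1.0)
        if joint.survey_spend > 1.0:
            with pytest.raises(ValueError):
                two_stage_removal(d_small, joint)


class TestSplitBudget:
    def test_zero_survey_cap_forces_none(self):
        data = tiny_problem(
            seed=41, budget=0.0, budget_survey=0.0, budget_removal=500.0
        )
        sol = solve(split_budget(data))
        assert all(m is None for m, _ in sol.chosen)

    def test_zero_removal_cap_forces_no_removal(self):
        data = tiny_problem(
            seed=42, budget=0.0, budget_survey=300.0, budget_removal=0.0
        )
        sol = solve(split_budget(data))
        assert np.all(sol.y1 <= 1e-9) and np.all(sol.y2 <= 1e-9)

    def test_split_at_joint_apportionment_matches_joint(self):
        data = tiny_problem(seed=43, J=3, S=3, budget=500.0)
        joint = solve(build_survey_removal(data), mip_rel_gap=1e-9)
        d_split = dataclasses.replace(
            data,
            budget_survey=joint.survey_spend + 1e-6,
            budget_removal=data.budget_total - joint.survey_spend + 1e-6,
        )
        sol = solve(split_budget(d_split), mip_rel_gap=1e-9)
        assert sol.objective == pytest.approx(joint.objective, rel=1e-5)

    def test_split_requires_both_caps(self):
        data = tiny_problem(seed=44)
        with pytest.raises(ValueError):
            split_budget(data)


class TestCVaR:
    def test_alpha_zero_equals_expected_value(self):
        data = tiny_problem(seed=51, J=3, S=5, budget=500.0)
        ev = solve(build_survey_removal(data), mip_rel_gap=1e-9)
        cv = solve(build_cvar(data, alpha=0.0), mip_rel_gap=1e-9)
        assert cv.objective == pytest.approx(ev.objective, abs=1e-6)

    def test_identical_scenarios_cvar_is_common_value(self):
        data = tiny_problem(seed=52, J=2, S=4)
        gamma = np.tile(data.scenarios.gamma[:1], (4, 1))
        data = dataclasses.replace(data, scenarios=ScenarioSet(gamma=gamma))
        cv = solve(build_cvar(data, alpha=0.6), mip_rel_gap=1e-9)
        assert cv.objective == pytest.approx(cv.z_s[0], rel=1e-6)
        assert np.allclose(cv.z_s, cv.z_s[0])

    def test_matches_sort_and_average_oracle(self):
        """alpha = 0.8 with S = 10: the CVaR optimum equals the brute-force
        search whose tail statistic averages the top two scenario values."""
        data = tiny_problem(seed=53, J=3, S=10, budget=500.0)
        cv = solve(build_cvar(data, alpha=0.8), mip_rel_gap=1e-9)
        orc = brute_force_oracle(data, alpha=0.8)
        assert cv.objective == pytest.approx(orc.objective, rel=1e-5)
        # the linearized objective equals the sorted-tail mean of its own plan
        top2 = np.sort(cv.z_s)[-2:].mean()
        assert cv.objective == pytest.approx(top2, rel=1e-6)

    def test_cvar_orderings(self):
        data = tiny_problem(seed=54, J=3, S=8, budget=600.0)
        alpha = 0.75
        ev = solve(build_survey_removal(data), mip_rel_gap=1e-9)
        cv = solve(build_cvar(data, alpha=alpha), mip_rel_gap=1e-9)
        # risk-averse plan sacrifices expectation ...
        assert cv.z_s.mean() >= ev.z_s.mean() - 1e-7
        # ... to improve the tail
        assert cvar_of(cv.z_s, alpha) <= cvar_of(ev.z_s, alpha) + 1e-7

    def test_invalid_alpha_rejected(self):
        data = tiny_problem(seed=55)
        with pytest.raises(ValueError):
            build_cvar(data, alpha=1.0)

    def test_cvar_of_is_tail_mean_at_integral_levels(self, rng):
        z = rng.normal(100.0, 10.0, size=20)
        assert cvar_of(z, 0.8) == pytest.approx(np.sort(z)[-4:].mean(), rel=1e-12)


class TestOracleGuards:
    def test_refuses_large_instances(self):
        data = tiny_problem(seed=61, J=3, S=12)
        with pytest.raises(ValueError):
            brute_force_oracle(data)
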