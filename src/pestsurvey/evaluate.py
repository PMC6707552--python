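"""Derived metrics, strategy comparisons, sensitivity analysis, run config.

This layer turns solved plans into the quantities a survey program manager
reads: expected numbers of removed (infested) trees, tabulations of
surveyed sites by method and sampling-rate bin, budget shares, and
elasticity-style sensitivities of the key outputs to +/-20% parameter
perturbations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import costs as _costs
from .costs import RemovalCostSpec
from .landscape import (
    DecayModel,
    HostDensitySpec,
    Landscape,
    ScenarioSet,
    make_landscape,
    mean_scenario,
    sample_scenarios,
)
from .optimize import (
    ProblemData,
    SamplingMenu,
    MenuOption,
    Solution,
    build_cvar,
    build_survey_removal,
    default_menu,
    solve,
    two_stage_removal,
    build_survey_only_p1,
    build_survey_only_p2,
)
from .sampling import nondetection_prob_array, pbeta_array

__all__ = [
    "SAMPLING_RATE_BINS",
    "RunConfig",
    "StrategyReport",
    "expected_removed_infested",
    "expected_removed_trees",
    "strategy_report",
    "strategy_comparison",
    "sensitivity_analysis",
    "build_problem",
]

#: Sampling-rate bins (trees inspected per site) used in reports.
SAMPLING_RATE_BINS = [(1, 5), (6, 25), (26, 50), (51, 100), (101, None)]


def _chosen_arrays(solution: Solution, data: ProblemData):
    """Per-site arrays (n, e, g) of the chosen options."""
    J = len(solution.chosen)
    n = np.zeros(J)
    e = np.zeros(J)
    g = np.zeros(J)
    for j, (method, nn) in enumerate(solution.chosen):
        if method is None:
            continue
        o = next(
            o
            for o in data.menu.options[j]
            if o.method == method and o.n == nn
        )
        n[j], e[j], g[j] = o.n, o.detection_rate, o.unit_cost
    return n, e, g


def expected_removed_infested(
    solution: Solution, scenarios: ScenarioSet, data: ProblemData
) -> float:
    """Expected number of *infested* trees removed by a plan, averaged over
    scenarios.

    Per site and scenario this is ``n*gamma*(1 - P*beta)*y1 +
    (N - n)*gamma*(1 - P)*y2`` — the detected-infested expectations of the
    sampled and unsampled populations times the removal fractions.
    """
    if scenarios.n_sites != data.landscape.n_sites:
        raise ValueError("scenario matrix does not match the landscape")
    gamma = scenarios.gamma
    N = data.landscape.hosts.astype(float)
    n, e, _ = _chosen_arrays(solution, data)
    P = nondetection_prob_array(gamma, e[None, :], n[None, :])
    pbeta = pbeta_array(gamma, e[None, :], n[None, :])
    per_site = (
        n[None, :] * gamma * (1.0 - pbeta) * solution.y1[None, :]
        + (N - n)[None, :] * gamma * (1.0 - P) * solution.y2[None, :]
    )
    return float(per_site.sum(axis=1).mean())


def expected_removed_trees(
    solution: Solution, scenarios: ScenarioSet, data: ProblemData
) -> tuple[float, float]:
    """Expected removed trees (infested or not) from the sampled and
    unsampled populations: removal happens only after a detection, so the
    counts carry the per-scenario detection probability ``1 - P``."""
    gamma = scenarios.gamma
    N = data.landscape.hosts.astype(float)
    n, e, _ = _chosen_arrays(solution, data)
    P = nondetection_prob_array(gamma, e[None, :], n[None, :])
    sampled = (n[None, :] * solution.y1[None, :] * (1.0 - P)).sum(axis=1).mean()
    unsampled = (
        ((N - n)[None, :] * solution.y2[None, :] * (1.0 - P)).sum(axis=1).mean()
    )
    return float(sampled), float(unsampled)


@dataclass
class StrategyReport:
    """Tabulated description of one solved strategy."""

    name: str
    budget: float
    objective: float
    table: pd.DataFrame  # rows: sampling-rate bin x method
    sites_surveyed: int
    trees_surveyed: int
    survey_spend: float
    survey_budget_fraction: float
    sites_with_removal: int
    expected_removed_sampled: float
    expected_removed_unsampled: float
    expected_removed_infested_trees: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["table"] = self.table.to_dict("records")
        return d


def strategy_report(
    name: str,
    solution: Solution,
    data: ProblemData,
    budget: float | None = None,
) -> StrategyReport:
    """Summarize a solved plan in the reporting layout of the case study:
    surveyed sites and budget shares by method and sampling-rate bin."""
    n, _, g = _chosen_arrays(solution, data)
    methods = [m for m, _ in solution.chosen]
    spend = n * g
    total_budget = budget if budget is not None else data.total_budget
    rows = []
    for lo, hi in SAMPLING_RATE_BINS:
        for method in (_costs.BRANCH, _costs.TRAP):
            mask = np.array(
                [
                    m == method and nn >= lo and (hi is None or nn <= hi)
                    for m, nn in zip(methods, n)
                ]
            )
            rows.append(
                {
                    "bin": f"{lo}-{hi if hi is not None else 'inf'}",
                    "method": method,
                    "sites": int(mask.sum()),
                    "trees": int(n[mask].sum()),
                    "survey_spend": float(spend[mask].sum()),
                    "budget_proportion": float(spend[mask].sum())
                    / total_budget,
                }
            )
    table = pd.DataFrame(rows)
    removed_s, removed_u = expected_removed_trees(solution, data.scenarios, data)
    tol = 1e-6
    return StrategyReport(
        name=name,
        budget=float(total_budget),
        objective=float(solution.objective),
        table=table,
        sites_surveyed=int(sum(1 for m in methods if m is not None)),
        trees_surveyed=int(n.sum()),
        survey_spend=float(spend.sum()),
        survey_budget_fraction=float(spend.sum()) / total_budget,
        sites_with_removal=int(
            np.sum((solution.y1 > tol) | (solution.y2 > tol))
        ),
        expected_removed_sampled=removed_s,
        expected_removed_unsampled=removed_u,
        expected_removed_infested_trees=expected_removed_infested(
            solution, data.scenarios, data
        ),
    )


def strategy_comparison(
    data: ProblemData,
    budgets: Sequence[float],
    alpha: float = 0.9,
    mip_rel_gap: float = 1e-4,
    include_cvar: bool = True,
    time_limit: float | None = None,
) -> list[StrategyReport]:
    """Compare the joint survey+removal plan against the survey-only
    strategies (problems 1 and 2, each followed by a two-stage removal
    re-solve at the joint plan's survey spend) and, optionally, the
    ambiguity-averse CVaR plan, for each budget.

    The survey budget handed to the survey-only problems is the survey
    spend of the joint optimum, so all strategies pay the same for surveys.
    """
    reports: list[StrategyReport] = []
    for B in budgets:
        d = dataclasses.replace(data, budget_total=float(B))
        joint = solve(
            build_survey_removal(d), mip_rel_gap=mip_rel_gap, time_limit=time_limit
        )
        if joint.status not in ("optimal", "gap-limit"):
            raise RuntimeError(f"joint solve failed at budget {B}: {joint.status}")
        reports.append(strategy_report(f"joint@{B:g}", joint, d))
        survey_budget = max(joint.survey_spend, 1e-9)
        for pname, builder in (("p1", build_survey_only_p1), ("p2", build_survey_only_p2)):
            d_survey = dataclasses.replace(d, budget_total=survey_budget)
            sol = solve(
                builder(d_survey), mip_rel_gap=mip_rel_gap, time_limit=time_limit
            )
            if sol.status not in ("optimal", "gap-limit"):
                raise RuntimeError(
                    f"{pname} solve failed at budget {B}: {sol.status}"
                )
            staged = two_stage_removal(d, sol, mip_rel_gap=mip_rel_gap)
            reports.append(
                strategy_report(f"{pname}+removal@{B:g}", staged, d)
            )
        if include_cvar:
            cv = solve(
                build_cvar(d, alpha=alpha),
                mip_rel_gap=mip_rel_gap,
                time_limit=time_limit,
            )
            if cv.status in ("optimal", "gap-limit"):
                reports.append(strategy_report(f"cvar@{B:g}", cv, d))
    return reports


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

SENSITIVITY_PARAMETERS = (
    "survey_cost",
    "detection_rate",
    "host_density",
    "infestation_rate",
    "removal_cost",
)


def _solution_outputs(solution: Solution, data: ProblemData) -> dict[str, float]:
    n, _, g = _chosen_arrays(solution, data)
    methods = [m for m, _ in solution.chosen]
    surveyed = n >= 1
    spend = float((n * g).sum())
    pct_sampled = (
        float((n * solution.y1).sum() / n.sum()) if n.sum() > 0 else 0.0
    )
    unsampled_pop = (data.landscape.hosts - n)[surveyed]
    pct_unsampled = (
        float(
            (unsampled_pop * solution.y2[surveyed]).sum() / unsampled_pop.sum()
        )
        if surveyed.any() and unsampled_pop.sum() > 0
        else 0.0
    )
    return {
        "objective": float(solution.objective),
        "sites_branch": float(sum(1 for m in methods if m == _costs.BRANCH)),
        "sites_trap": float(sum(1 for m in methods if m == _costs.TRAP)),
        "survey_budget_fraction": spend / data.total_budget,
        "pct_removed_sampled": pct_sampled,
        "pct_removed_unsampled": pct_unsampled,
    }


def _perturb(data: ProblemData, parameter: str, factor: float) -> ProblemData:
    """Rescale one named parameter of a problem by ``factor``."""
    if parameter == "survey_cost":
        menu = SamplingMenu(
            options=[
                [
                    o
                    if o.method is None
                    else MenuOption(o.method, o.n, o.unit_cost * factor, o.detection_rate)
                    for o in opts
                ]
                for opts in data.menu.options
            ]
        )
        return dataclasses.replace(data, menu=menu)
    if parameter == "detection_rate":
        menu = SamplingMenu(
            options=[
                [
                    o
                    if o.method is None
                    else MenuOption(
                        o.method,
                        o.n,
                        o.unit_cost,
                        min(1.0, o.detection_rate * factor),
                    )
                    for o in opts
                ]
                for opts in data.menu.options
            ]
        )
        return dataclasses.replace(data, menu=menu)
    if parameter == "removal_cost":
        return dataclasses.replace(
            data,
            removal_cost=RemovalCostSpec(
                unit_cost=data.removal_cost.unit_cost * factor
            ),
        )
    if parameter == "infestation_rate":
        gamma = np.clip(data.scenarios.gamma * factor, 0.0, 1.0)
        return dataclasses.replace(
            data, scenarios=ScenarioSet(gamma=gamma, seed=data.scenarios.seed)
        )
    if parameter == "host_density":
        sites = data.landscape.sites.copy()
        sites["hosts_small"] = np.round(
            sites["hosts_small"].to_numpy() * factor
        ).astype(int)
        sites["hosts_large"] = np.round(
            sites["hosts_large"].to_numpy() * factor
        ).astype(int)
        land = Landscape(sites=sites, cell_size_km=data.landscape.cell_size_km)
        N = land.hosts
        menu = SamplingMenu(
            options=[
                [o for o in opts if o.n <= N[j]]
                for j, opts in enumerate(data.menu.options)
            ]
        )
        return dataclasses.replace(data, landscape=land, menu=menu)
    raise ValueError(f"unknown sensitivity parameter {parameter!r}")


def sensitivity_analysis(
    data: ProblemData,
    parameters: Sequence[str] = SENSITIVITY_PARAMETERS,
    delta: float = 0.2,
    mip_rel_gap: float = 1e-4,
    solve_fn: Callable[[ProblemData], Solution] | None = None,
) -> pd.DataFrame:
    """Elasticity-style sensitivity table.

    Each parameter is rescaled globally by ``1 +/- delta``, the problem is
    re-solved, and every output's sensitivity is ``|relative output
    change| / delta``, averaged over the two directions. An infeasible
    re-solve leaves the cell missing (NaN) rather than failing the table.
    """
    if solve_fn is None:
        solve_fn = lambda d: solve(build_survey_removal(d), mip_rel_gap=mip_rel_gap)
    base_sol = solve_fn(data)
    if base_sol.status not in ("optimal", "gap-limit"):
        raise RuntimeError(f"base case did not solve: {base_sol.status}")
    base_out = _solution_outputs(base_sol, data)
    rows = {}
    for param in parameters:
        ratios: dict[str, list[float]] = {k: [] for k in base_out}
        for factor in (1.0 + delta, 1.0 - delta):
            try:
                d2 = _perturb(data, param, factor)
                sol = solve_fn(d2)
            except Exception:
                sol = None
            if sol is None or sol.status not in ("optimal", "gap-limit"):
                continue
            out = _solution_outputs(sol, d2)
            for k, base_v in base_out.items():
                if base_v != 0.0:
                    ratios[k].append(abs(out[k] - base_v) / abs(base_v) / delta)
                elif out[k] == 0.0:
                    ratios[k].append(0.0)
        rows[param] = {
            k: (float(np.mean(v)) if v else float("nan"))
            for k, v in ratios.items()
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of a full run, serializable to JSON/YAML."""

    n_rows: int = 8
    n_cols: int = 8
    host_median: float = 120.0
    host_sigma_log: float = 0.9
    corridor_cols: tuple[int, ...] = ()
    corridor_multiplier: float = 4.0
    seed_cells: tuple[tuple[int, int], ...] = ((0, 0),)
    size_mix: tuple[float, float] = (0.8, 0.2)
    mu0: float = 0.3
    lam: float = 0.35
    kappa: float = 6.0
    gamma_floor: float = 0.002
    n_scenarios: int = 200
    landscape_seed: int = 0
    scenario_seed: int = 1
    menu_levels: tuple[int, ...] = (1, 2, 5, 10, 25, 50, 100)
    unit_costs: dict = field(
        default_factory=lambda: {
            "trap_small": 87.21,
            "trap_large": 124.42,
            "branch_small": 128.90,
            "branch_large": 249.60,
        }
    )
    detection_rates: dict = field(
        default_factory=lambda: {"branch": 0.7, "trap": 0.5}
    )
    removal_cost: float = 400.0
    budget_total: float = 200_000.0
    budget_survey: float | None = None
    budget_removal: float | None = None
    objective_mode: str = "expected"  # or "cvar"
    alpha: float = 0.9
    mip_rel_gap: float = 1e-4
    time_limit: float | None = None
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["corridor_cols"] = list(self.corridor_cols)
        d["seed_cells"] = [list(c) for c in self.seed_cells]
        d["size_mix"] = list(self.size_mix)
        d["menu_levels"] = list(self.menu_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "corridor_cols" in d:
            d["corridor_cols"] = tuple(d["corridor_cols"])
        if "seed_cells" in d:
            d["seed_cells"] = tuple(tuple(c) for c in d["seed_cells"])
        if "size_mix" in d:
            d["size_mix"] = tuple(d["size_mix"])
        if "menu_levels" in d:
            d["menu_levels"] = tuple(d["menu_levels"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def build_problem(config: RunConfig) -> ProblemData:
    """Materialize a ProblemData from a run configuration."""
    land = make_landscape(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        host_density_spec=HostDensitySpec(
            median=config.host_median,
            sigma_log=config.host_sigma_log,
            corridor_cols=tuple(config.corridor_cols),
            corridor_multiplier=config.corridor_multiplier,
        ),
        seed_cells=config.seed_cells,
        size_mix=config.size_mix,
        rng_seed=config.landscape_seed,
    )
    scen = sample_scenarios(
        land,
        DecayModel(
            mu0=config.mu0,
            lam=config.lam,
            kappa=config.kappa,
            gamma_floor=config.gamma_floor,
        ),
        S=config.n_scenarios,
        rng_seed=config.scenario_seed,
    )
    uc = config.unit_costs
    menu = default_menu(
        land,
        unit_costs={
            (_costs.TRAP, _costs.SMALL): uc["trap_small"],
            (_costs.TRAP, _costs.LARGE): uc["trap_large"],
            (_costs.BRANCH, _costs.SMALL): uc["branch_small"],
            (_costs.BRANCH, _costs.LARGE): uc["branch_large"],
        },
        detection_rates=dict(config.detection_rates),
        levels=config.menu_levels,
    )
    return ProblemData(
        landscape=land,
        scenarios=scen,
        menu=menu,
        removal_cost=RemovalCostSpec(unit_cost=config.removal_cost),
        budget_total=config.budget_total,
        budget_survey=config.budget_survey,
        budget_removal=config.budget_removal,
    )
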