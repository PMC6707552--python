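"""Scenario-based MILP allocating pest surveys and host-tree removals.

The decision problem: for every 1-km survey site choose one sampling option
(a survey method and the number of trees to inspect, or no survey) and,
for surveyed sites, the fractions of sampled (``y1``) and unsampled
(``y2``) trees to remove if the survey detects the infestation, so as to
minimize the expected number of infested trees remaining in the landscape.
Uncertainty about where the pest has spread enters through a set of
infestation scenarios: per-scenario budget constraints cap survey spending
plus *expected* removal spending (removal only happens after a detection,
an event with probability ``1 - P`` in each scenario).

Model anatomy (per site ``j``, option ``m``, scenario ``s``):

* binary ``x[j,m]`` selects exactly one option per site;
* continuous ``y1[j,m], y2[j,m] in [0,1]`` are removal fractions, linked
  by ``y <= x`` so removal requires a survey;
* the objective averages over scenarios the expected slippage plus the
  post-removal residual of each site;
* survey-only variants drop the removal variables and minimize either the
  expected number of undetected-infested sites (problem 1) or the expected
  slippage (problem 2) under a survey-spend budget;
* the ambiguity-averse variant minimizes the conditional value-at-risk
  CVaR_alpha of the per-scenario objective through the standard
  linearization (an auxiliary VaR level plus per-scenario tail excesses).

Models are solved with the HiGHS branch-and-bound solver via
``scipy.optimize.milp``; a brute-force oracle (exhaustive survey
assignments with an inner LP or grid search over removal fractions) is
provided for auditing small instances, and models can be exported to the
CPLEX LP text format for cross-solver checks.
"""

from __future__ import annotations

import contextlib
import itertools
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from . import costs as _costs
from .costs import RemovalCostSpec, site_weighted_unit_cost
from .landscape import Landscape, ScenarioSet
from .sampling import nondetection_prob_array, pbeta_array

__all__ = [
    "MenuOption",
    "NONE_OPTION",
    "SamplingMenu",
    "default_menu",
    "ProblemData",
    "ModelSpec",
    "Solution",
    "build_survey_removal",
    "build_survey_only_p1",
    "build_survey_only_p2",
    "build_cvar",
    "split_budget",
    "two_stage_removal",
    "solve",
    "evaluate_plan",
    "cvar_of",
    "brute_force_oracle",
    "write_lp",
]

#: Default sampling levels (trees inspected per site), intersected with
#: [1, N_j] per site. Spans the reporting bins 1-5 / 6-25 / 26-50 / 51-100.
DEFAULT_LEVELS = (1, 2, 5, 10, 25, 50, 100)

_STATUS = {0: "optimal", 1: "gap-limit", 2: "infeasible", 3: "unbounded"}


@contextlib.contextmanager
def _quiet_native_stdout(enabled: bool = True):
    """Silence C-level chatter from the native solver library.

    HiGHS occasionally writes diagnostics directly to file descriptors 1
    and 2, bypassing ``sys.stdout``/``sys.stderr``; redirect both to
    /dev/null for the duration of the solve. Solver failures still surface
    through the result object."""
    if not enabled:
        yield
        return
    for stream in (sys.stdout, sys.stderr):
        try:
            stream.flush()
        except (OSError, ValueError):
            pass
    saved = {}
    try:
        for fd in (1, 2):
            saved[fd] = os.dup(fd)
    except OSError:
        for fd, dup in saved.items():
            os.close(dup)
        yield
        return
    try:
        with open(os.devnull, "w") as devnull:
            for fd in saved:
                os.dup2(devnull.fileno(), fd)
            yield
    finally:
        for fd, dup in saved.items():
            os.dup2(dup, fd)
            os.close(dup)


@dataclass(frozen=True)
class MenuOption:
    """One sampling option: method, sample size, unit cost, detection rate."""

    method: str | None
    n: int
    unit_cost: float
    detection_rate: float

    def __post_init__(self) -> None:
        if self.method is None:
            if self.n != 0 or self.unit_cost != 0.0:
                raise ValueError("the no-survey option must have n = 0, cost 0")
        else:
            if self.n < 1:
                raise ValueError("survey options must sample at least one tree")
            if not 0.0 < self.detection_rate <= 1.0:
                raise ValueError("detection_rate must be in (0, 1]")
            if self.unit_cost < 0:
                raise ValueError("unit_cost must be nonnegative")


NONE_OPTION = MenuOption(method=None, n=0, unit_cost=0.0, detection_rate=0.0)


@dataclass
class SamplingMenu:
    """Per-site ordered option lists; exactly one no-survey option each."""

    options: list[list[MenuOption]]

    def __post_init__(self) -> None:
        for j, opts in enumerate(self.options):
            n_none = sum(1 for o in opts if o.method is None)
            if n_none != 1:
                raise ValueError(
                    f"site {j}: expected exactly one no-survey option, got {n_none}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.options)


def default_menu(
    landscape: Landscape,
    unit_costs: dict[tuple[str, str], float] | None = None,
    detection_rates: dict[str, float] | None = None,
    levels: Sequence[int] = DEFAULT_LEVELS,
) -> SamplingMenu:
    """Build the default per-site menu: no-survey plus each method crossed
    with every sampling level that fits the site's host count.

    Each method's per-tree cost at a site is the host-composition-weighted
    mean of its small/large size-class costs.
    """
    unit_costs = unit_costs or _costs.DEFAULT_UNIT_COSTS
    detection_rates = detection_rates or _costs.DEFAULT_DETECTION_RATES
    options: list[list[MenuOption]] = []
    small = landscape.sites["hosts_small"].to_numpy()
    large = landscape.sites["hosts_large"].to_numpy()
    for j in range(landscape.n_sites):
        N_j = int(small[j] + large[j])
        opts = [NONE_OPTION]
        if N_j >= 1:
            for method in (_costs.TRAP, _costs.BRANCH):
                g = site_weighted_unit_cost(
                    int(small[j]),
                    int(large[j]),
                    unit_costs[(method, _costs.SMALL)],
                    unit_costs[(method, _costs.LARGE)],
                )
                for n in levels:
                    if n <= N_j:
                        opts.append(
                            MenuOption(
                                method=method,
                                n=int(n),
                                unit_cost=g,
                                detection_rate=detection_rates[method],
                            )
                        )
        options.append(opts)
    return SamplingMenu(options=options)


@dataclass
class ProblemData:
    """Everything a model build needs: landscape, scenarios, menu, costs,
    budget(s)."""

    landscape: Landscape
    scenarios: ScenarioSet
    menu: SamplingMenu
    removal_cost: RemovalCostSpec = field(default_factory=RemovalCostSpec)
    budget_total: float = 0.0
    budget_survey: float | None = None
    budget_removal: float | None = None

    def __post_init__(self) -> None:
        if self.scenarios.n_sites != self.landscape.n_sites:
            raise ValueError(
                "scenario matrix has "
                f"{self.scenarios.n_sites} sites, landscape has "
                f"{self.landscape.n_sites}"
            )
        if self.menu.n_sites != self.landscape.n_sites:
            raise ValueError("menu and landscape site counts differ")
        if self.budget_total <= 0 and self.budget_survey is None:
            raise ValueError("a positive budget_total (or split budgets) is required")
        if (self.budget_survey is None) != (self.budget_removal is None):
            raise ValueError("split budgets require both survey and removal caps")
        if self.budget_survey is not None:
            if self.budget_survey < 0 or self.budget_removal < 0:
                raise ValueError("split budgets must be nonnegative")
        N = self.landscape.hosts
        for j, opts in enumerate(self.menu.options):
            for o in opts:
                if o.n > N[j]:
                    raise ValueError(
                        f"site {j}: option samples {o.n} trees but the site has "
                        f"only {N[j]}"
                    )

    @property
    def total_budget(self) -> float:
        if self.budget_total > 0:
            return self.budget_total
        return float(self.budget_survey + self.budget_removal)


class _Tables:
    """Flattened coefficient tables over (site, option) pairs x scenarios."""

    def __init__(self, data: ProblemData):
        land = data.landscape
        gamma = data.scenarios.gamma  # (S, J)
        opts = data.menu.options
        j_idx, n, g, e, local = [], [], [], [], []
        for j, site_opts in enumerate(opts):
            for m, o in enumerate(site_opts):
                j_idx.append(j)
                local.append(m)
                n.append(o.n)
                g.append(o.unit_cost)
                e.append(o.detection_rate)
        self.j_idx = np.asarray(j_idx)
        self.local = np.asarray(local)
        self.n = np.asarray(n, dtype=float)
        self.g = np.asarray(g, dtype=float)
        self.e = np.asarray(e, dtype=float)
        self.K = len(j_idx)
        self.S = gamma.shape[0]
        self.N = land.hosts.astype(float)[self.j_idx]  # (K,)
        self.c_removal = data.removal_cost.unit_cost

        gam = gamma[:, self.j_idx]  # (S, K)
        P = nondetection_prob_array(gam, self.e[None, :], self.n[None, :])
        pbeta = pbeta_array(gam, self.e[None, :], self.n[None, :])
        n_, N_ = self.n[None, :], self.N[None, :]
        self.P = P
        self.E = P * gam * (N_ - n_) + n_ * gam * pbeta  # expected slippage
        self.F0 = gam * (N_ - n_) * (1.0 - P) + n_ * gam * (1.0 - pbeta)
        # objective coefficients, scenario-wise (Eq 16 terms)
        self.coef_x = self.E + self.F0  # == gamma * N
        self.coef_y1 = -(n_ * gam * (1.0 - pbeta))
        self.coef_y2 = -((N_ - n_) * gam * (1.0 - P))
        # budget coefficients: expected removal spend conditional on detection
        self.rm_y1 = self.c_removal * (1.0 - P) * n_
        self.rm_y2 = self.c_removal * (1.0 - P) * (N_ - n_)
        self.survey_x = self.n * self.g  # (K,)
        self.is_survey = self.n >= 1
        # y-variable indexing: one (y1, y2) pair per survey option
        self.y_of = np.full(self.K, -1)
        self.y_of[self.is_survey] = np.arange(int(self.is_survey.sum()))
        self.K1 = int(self.is_survey.sum())


@dataclass
class ModelSpec:
    """A fully assembled linear model ready for the solver.

    ``scenario_obj`` holds one objective-coefficient row per scenario
    (on the decision variables only) so that per-scenario objective values
    ``z_s`` can be read off any variable vector.
    """

    kind: str
    c: np.ndarray
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    labels_ub: list[str]
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    labels_eq: list[str]
    integrality: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    scenario_obj: np.ndarray
    tables: _Tables
    data: ProblemData
    n_x: int
    n_y: int
    alpha: float | None = None

    @property
    def n_var(self) -> int:
        return self.c.size

    @property
    def labels(self) -> list[str]:
        return self.labels_ub + self.labels_eq

    def fix_x(self, x_values: np.ndarray) -> "ModelSpec":
        """Return a copy with the survey selection variables frozen."""
        lb = self.lb.copy()
        ub = self.ub.copy()
        xv = np.round(np.asarray(x_values, dtype=float))
        lb[: self.n_x] = xv
        ub[: self.n_x] = xv
        return ModelSpec(
            kind=self.kind + "-fixed-x",
            c=self.c,
            A_ub=self.A_ub,
            b_ub=self.b_ub,
            labels_ub=self.labels_ub,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            labels_eq=self.labels_eq,
            integrality=self.integrality,
            lb=lb,
            ub=ub,
            scenario_obj=self.scenario_obj,
            tables=self.tables,
            data=self.data,
            n_x=self.n_x,
            n_y=self.n_y,
            alpha=self.alpha,
        )


@dataclass
class Solution:
    """A solved survey/removal plan.

    ``chosen`` lists one (method, n) per site; ``y1``/``y2`` are the
    removal fractions of the chosen option (0 where no survey). ``z_s``
    are per-scenario objective values; for expected-value runs the
    reported ``objective`` is their mean, for CVaR runs it is the CVaR.
    """

    status: str
    objective: float
    chosen: list[tuple[str | None, int]]
    y1: np.ndarray
    y2: np.ndarray
    z_s: np.ndarray
    survey_spend: float
    removal_spend: np.ndarray
    mip_gap: float
    x: np.ndarray
    var: np.ndarray
    kind: str

    @property
    def expected_objective(self) -> float:
        return float(self.z_s.mean())

    def summary(self) -> dict:
        qs = np.quantile(self.z_s, [0.0, 0.25, 0.5, 0.75, 0.9, 1.0])
        return {
            "status": self.status,
            "kind": self.kind,
            "objective": self.objective,
            "expected_objective": self.expected_objective,
            "z_s_quantiles": {
                "min": qs[0],
                "q25": qs[1],
                "median": qs[2],
                "q75": qs[3],
                "q90": qs[4],
                "max": qs[5],
            },
            "survey_spend": self.survey_spend,
            "mean_removal_spend": float(self.removal_spend.mean()),
            "max_removal_spend": float(self.removal_spend.max()),
            "mip_gap": self.mip_gap,
            "sites_surveyed": sum(1 for m, _ in self.chosen if m is not None),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "site": np.arange(len(self.chosen)),
                "method": [m for m, _ in self.chosen],
                "n": [n for _, n in self.chosen],
                "y1": self.y1,
                "y2": self.y2,
            }
        )


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def _assemble(
    kind: str,
    data: ProblemData,
    with_removal: bool,
    budget_mode: str,
    cvar_alpha: float | None = None,
) -> ModelSpec:
    """Shared assembly for all model variants.

    budget_mode: "joint" (survey + expected removal <= B per scenario,
    with optional split caps), or "survey" (survey spend <= B, one row).
    """
    t = _Tables(data)
    J = data.landscape.n_sites
    S = t.S
    n_x = t.K
    n_y = 2 * t.K1 if with_removal else 0
    n_aux = (1 + S) if cvar_alpha is not None else 0
    n_var = n_x + n_y + n_aux
    y1_off = n_x
    y2_off = n_x + t.K1
    eta_idx = n_x + n_y
    u_off = eta_idx + 1

    # per-scenario objective rows on the decision variables
    scen = np.zeros((S, n_var))
    if kind == "p1":
        scen[:, :n_x] = t.P
    elif kind == "p2":
        scen[:, :n_x] = t.E
    else:
        scen[:, :n_x] = t.coef_x
        if with_removal:
            for k in np.flatnonzero(t.is_survey):
                y = t.y_of[k]
                scen[:, y1_off + y] = t.coef_y1[:, k]
                scen[:, y2_off + y] = t.coef_y2[:, k]

    rows_ub: list[tuple[np.ndarray, np.ndarray]] = []  # (cols, vals)
    b_ub: list[float] = []
    labels_ub: list[str] = []

    if budget_mode == "survey":
        cols = np.arange(n_x)
        rows_ub.append((cols, t.survey_x.copy()))
        b_ub.append(data.total_budget)
        labels_ub.append("budget-22")
    else:
        B = data.total_budget
        for s in range(S):
            cols = [np.arange(n_x)]
            vals = [t.survey_x]
            if with_removal:
                kk = np.flatnonzero(t.is_survey)
                cols.append(y1_off + t.y_of[kk])
                vals.append(t.rm_y1[s, kk])
                cols.append(y2_off + t.y_of[kk])
                vals.append(t.rm_y2[s, kk])
            rows_ub.append((np.concatenate(cols), np.concatenate(vals)))
            b_ub.append(B)
            labels_ub.append(f"budget-19[s={s}]")
        if data.budget_survey is not None:
            rows_ub.append((np.arange(n_x), t.survey_x.copy()))
            b_ub.append(float(data.budget_survey))
            labels_ub.append("budget-survey-cap")
            if with_removal:
                kk = np.flatnonzero(t.is_survey)
                for s in range(S):
                    cols = np.concatenate(
                        [y1_off + t.y_of[kk], y2_off + t.y_of[kk]]
                    )
                    vals = np.concatenate([t.rm_y1[s, kk], t.rm_y2[s, kk]])
                    rows_ub.append((cols, vals))
                    b_ub.append(float(data.budget_removal))
                    labels_ub.append(f"budget-removal-cap[s={s}]")

    if with_removal:
        # tight linking y <= x (stronger than, and implying, the printed
        # y <= x * n form)
        for k in np.flatnonzero(t.is_survey):
            y = t.y_of[k]
            rows_ub.append(
                (np.array([y1_off + y, k]), np.array([1.0, -1.0]))
            )
            b_ub.append(0.0)
            labels_ub.append(f"linking-18-y1[j={t.j_idx[k]},m={t.local[k]}]")
            rows_ub.append(
                (np.array([y2_off + y, k]), np.array([1.0, -1.0]))
            )
            b_ub.append(0.0)
            labels_ub.append(f"linking-18-y2[j={t.j_idx[k]},m={t.local[k]}]")

    if cvar_alpha is not None:
        # tail_excess_s >= z_s - eta  <=>  scen_s . v - eta - u_s <= 0
        for s in range(S):
            cols = np.flatnonzero(scen[s])
            vals = scen[s, cols]
            cols = np.concatenate([cols, [eta_idx, u_off + s]])
            vals = np.concatenate([vals, [-1.0, -1.0]])
            rows_ub.append((cols, vals))
            b_ub.append(0.0)
            labels_ub.append(f"cvar-tail[s={s}]")

    # one-option-20 equality rows
    rows_eq: list[tuple[np.ndarray, np.ndarray]] = []
    labels_eq = []
    for j in range(J):
        cols = np.flatnonzero(t.j_idx == j)
        rows_eq.append((cols, np.ones(cols.size)))
        labels_eq.append(f"one-option-20[j={j}]")
    b_eq = np.ones(J)

    def _to_csr(rows, n_rows):
        data_, ri, ci = [], [], []
        for i, (cols, vals) in enumerate(rows):
            ri.extend([i] * len(cols))
            ci.extend(cols.tolist())
            data_.extend(vals.tolist())
        return sparse.csr_matrix(
            (data_, (ri, ci)), shape=(n_rows, n_var)
        )

    A_ub = _to_csr(rows_ub, len(rows_ub))
    A_eq = _to_csr(rows_eq, len(rows_eq))

    # objective
    c = np.zeros(n_var)
    if cvar_alpha is not None:
        c[eta_idx] = 1.0
        c[u_off:] = 1.0 / ((1.0 - cvar_alpha) * S)
    else:
        c[:] = scen.mean(axis=0)

    integrality = np.zeros(n_var)
    integrality[:n_x] = 1
    lb = np.zeros(n_var)
    ub = np.ones(n_var)
    if cvar_alpha is not None:
        lb[eta_idx] = -np.inf
        ub[eta_idx] = np.inf
        ub[u_off:] = np.inf

    return ModelSpec(
        kind=kind if cvar_alpha is None else "cvar",
        c=c,
        A_ub=A_ub,
        b_ub=np.asarray(b_ub, dtype=float),
        labels_ub=labels_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        labels_eq=labels_eq,
        integrality=integrality,
        lb=lb,
        ub=ub,
        scenario_obj=scen,
        tables=t,
        data=data,
        n_x=n_x,
        n_y=n_y,
        alpha=cvar_alpha,
    )


def build_survey_removal(data: ProblemData) -> ModelSpec:
    """Joint survey + removal model minimizing the expected number of
    infested trees remaining, with a per-scenario budget on survey spend
    plus expected removal spend."""
    if data.scenarios.n_scenarios < 1:
        raise ValueError("need at least one scenario")
    return _assemble("joint", data, with_removal=True, budget_mode="joint")


def build_survey_only_p1(data: ProblemData) -> ModelSpec:
    """Survey-only problem 1: minimize the expected number of sites whose
    infestation goes undetected (sum of non-detection probabilities)."""
    return _assemble("p1", data, with_removal=False, budget_mode="survey")


def build_survey_only_p2(data: ProblemData) -> ModelSpec:
    """Survey-only problem 2: minimize the expected slippage (infested
    trees in sites declared clean or left unsurveyed)."""
    return _assemble("p2", data, with_removal=False, budget_mode="survey")


def build_cvar(data: ProblemData, alpha: float = 0.9) -> ModelSpec:
    """Ambiguity-averse variant: minimize CVaR_alpha of the per-scenario
    objective of the joint survey + removal model."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    return _assemble(
        "joint", data, with_removal=True, budget_mode="joint", cvar_alpha=alpha
    )


def split_budget(data: ProblemData) -> ModelSpec:
    """Joint model with separate survey and removal budget caps (on top of
    the per-scenario total-budget constraint)."""
    if data.budget_survey is None or data.budget_removal is None:
        raise ValueError("split_budget requires both budget_survey and budget_removal")
    return _assemble("joint", data, with_removal=True, budget_mode="joint")


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def solve(
    model: ModelSpec,
    mip_rel_gap: float = 1e-4,
    time_limit: float | None = None,
    disp: bool = False,
) -> Solution:
    """Solve a model with HiGHS branch-and-bound and unpack the plan.

    The returned status is one of ``optimal``, ``gap-limit``,
    ``infeasible``, ``unbounded`` or ``failed``; solver failures carry the
    solver message in the exception, never a silent bad answer.
    """
    constraints = []
    if model.A_ub.shape[0]:
        constraints.append(
            LinearConstraint(model.A_ub, -np.inf, model.b_ub)
        )
    if model.A_eq.shape[0]:
        constraints.append(LinearConstraint(model.A_eq, model.b_eq, model.b_eq))
    options: dict = {"mip_rel_gap": mip_rel_gap, "disp": disp}
    if time_limit is not None:
        options["time_limit"] = time_limit
    with _quiet_native_stdout(enabled=not disp):
        res = milp(
            c=model.c,
            constraints=constraints,
            integrality=model.integrality,
            bounds=Bounds(model.lb, model.ub),
            options=options,
        )
    status = _STATUS.get(res.status, "failed")
    if res.x is None:
        return Solution(
            status=status,
            objective=float("nan"),
            chosen=[(None, 0)] * model.data.landscape.n_sites,
            y1=np.zeros(model.data.landscape.n_sites),
            y2=np.zeros(model.data.landscape.n_sites),
            z_s=np.full(model.tables.S, np.nan),
            survey_spend=float("nan"),
            removal_spend=np.full(model.tables.S, np.nan),
            mip_gap=float("nan"),
            x=np.zeros(model.n_x),
            var=np.zeros(model.n_var),
            kind=model.kind,
        )
    return _unpack(model, res)


def _unpack(model: ModelSpec, res) -> Solution:
    t = model.tables
    v = np.asarray(res.x, dtype=float)
    x = v[: model.n_x]
    J = model.data.landscape.n_sites
    chosen: list[tuple[str | None, int]] = []
    y1 = np.zeros(J)
    y2 = np.zeros(J)
    opts = model.data.menu.options
    y1_off = model.n_x
    y2_off = model.n_x + t.K1
    for j in range(J):
        ks = np.flatnonzero(t.j_idx == j)
        k = ks[np.argmax(x[ks])]
        o = opts[j][t.local[k]]
        chosen.append((o.method, o.n))
        if model.n_y and t.y_of[k] >= 0 and x[k] > 0.5:
            y1[j] = float(np.clip(v[y1_off + t.y_of[k]], 0.0, 1.0))
            y2[j] = float(np.clip(v[y2_off + t.y_of[k]], 0.0, 1.0))
    z_s = model.scenario_obj @ v
    survey_spend = float(t.survey_x @ np.round(x))
    removal = np.zeros(t.S)
    if model.n_y:
        kk = np.flatnonzero(t.is_survey)
        yv1 = v[y1_off + t.y_of[kk]] * np.round(x[kk])
        yv2 = v[y2_off + t.y_of[kk]] * np.round(x[kk])
        removal = t.rm_y1[:, kk] @ yv1 + t.rm_y2[:, kk] @ yv2
    mip_gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    if model.alpha is not None:
        objective = float(res.fun)
    else:
        objective = float(z_s.mean())
    return Solution(
        status=_STATUS.get(res.status, "failed"),
        objective=objective,
        chosen=chosen,
        y1=y1,
        y2=y2,
        z_s=z_s,
        survey_spend=survey_spend,
        removal_spend=removal,
        mip_gap=mip_gap,
        x=x,
        var=v,
        kind=model.kind,
    )


def two_stage_removal(
    data: ProblemData, fixed_survey: Solution, mip_rel_gap: float = 1e-4
) -> Solution:
    """Freeze a survey plan (e.g. from a survey-only problem) and
    re-optimize only the removal fractions under the joint objective and
    per-scenario budget. The frozen problem is an LP in ``y``."""
    model = build_survey_removal(data)
    x = _map_x(model, fixed_survey)
    spend = float(model.tables.survey_x @ x)
    if spend > data.total_budget + 1e-6:
        raise ValueError(
            f"fixed survey plan spends {spend:.2f}, exceeding the budget "
            f"{data.total_budget:.2f}"
        )
    return solve(model.fix_x(x), mip_rel_gap=mip_rel_gap)


def _map_x(model: ModelSpec, solution: Solution) -> np.ndarray:
    """Map a solution's chosen (method, n) per site onto this model's
    x-vector (menus must offer the chosen options)."""
    t = model.tables
    opts = model.data.menu.options
    x = np.zeros(model.n_x)
    for j, (method, n) in enumerate(solution.chosen):
        ks = np.flatnonzero(t.j_idx == j)
        match = [
            k
            for k in ks
            if opts[j][t.local[k]].method == method and opts[j][t.local[k]].n == n
        ]
        if not match:
            raise ValueError(f"site {j}: option ({method}, {n}) not in menu")
        x[match[0]] = 1.0
    return x


# ---------------------------------------------------------------------------
# independent evaluation and oracles
# ---------------------------------------------------------------------------


def evaluate_plan(data: ProblemData, solution: Solution) -> np.ndarray:
    """Recompute per-scenario objective values of a plan from first
    principles (site-by-site slippage + post-removal residual), without
    touching the model's coefficient matrices."""
    from .sampling import (
        RemovalFractions,
        SiteSamplingInputs,
        expected_slippage,
        residual_after_removal,
    )

    gamma = data.scenarios.gamma
    N = data.landscape.hosts
    S = gamma.shape[0]
    z = np.zeros(S)
    for j, (method, n) in enumerate(solution.chosen):
        e = 0.0
        if method is not None:
            e = next(
                o.detection_rate
                for o in data.menu.options[j]
                if o.method == method and o.n == n
            )
        rem = RemovalFractions(y1=float(solution.y1[j]), y2=float(solution.y2[j]))
        for s in range(S):
            inp = SiteSamplingInputs(
                gamma=float(gamma[s, j]), e=e, n=int(n), N=int(N[j])
            )
            z[s] += expected_slippage(inp) + residual_after_removal(inp, rem)
    return z


def cvar_of(z_s: np.ndarray, alpha: float) -> float:
    """CVaR_alpha of an equally weighted scenario sample: the minimum over
    eta of ``eta + mean(max(z - eta, 0)) / (1 - alpha)`` (Rockafellar-
    Uryasev form)."""
    z = np.sort(np.asarray(z_s, dtype=float))
    S = z.size
    best = np.inf
    for eta in np.concatenate([z, [z[-1]]]):
        val = eta + np.maximum(z - eta, 0.0).sum() / ((1.0 - alpha) * S)
        best = min(best, float(val))
    return best


def brute_force_oracle(
    data: ProblemData,
    problem: str = "joint",
    alpha: float | None = None,
    y_method: str = "lp",
    max_assignments: int = 200_000,
) -> Solution:
    """Exhaustive oracle for tiny instances.

    Enumerates every survey assignment (one menu option per site); for the
    joint problem optimizes removal fractions per assignment by an inner
    LP (``y_method='lp'``) or a 0.01-step grid search (``y_method='grid'``,
    at most two surveyed sites); returns the best feasible plan. Refuses
    instances beyond ~4 sites x 3 options x 10 scenarios.
    """
    J = data.landscape.n_sites
    S = data.scenarios.n_scenarios
    sizes = [len(o) for o in data.menu.options]
    if J > 4 or max(sizes) > 4 or S > 10:
        raise ValueError(
            "instance too large for the brute-force oracle "
            f"(J={J}, max options={max(sizes)}, S={S})"
        )
    if int(np.prod(sizes)) > max_assignments:
        raise ValueError("too many assignments to enumerate")

    t = _Tables(data)
    B = data.total_budget
    site_ks = [np.flatnonzero(t.j_idx == j) for j in range(J)]
    best = None
    for combo in itertools.product(*[range(s) for s in sizes]):
        ks = np.array([site_ks[j][m] for j, m in enumerate(combo)])
        spend = float(t.survey_x[ks].sum())
        if problem in ("p1", "p2"):
            if spend > B + 1e-9:
                continue
            z_s = (t.P if problem == "p1" else t.E)[:, ks].sum(axis=1)
            obj = float(z_s.mean())
            cand = (obj, ks, np.zeros(J), np.zeros(J), z_s, spend, np.zeros(S))
        else:
            res = _inner_removal(
                t, ks, B, data, alpha=alpha, y_method=y_method
            )
            if res is None:
                continue
            obj, y1, y2, z_s, removal = res
            cand = (obj, ks, y1, y2, z_s, spend, removal)
        if best is None or cand[0] < best[0] - 1e-12:
            best = cand
    if best is None:
        return Solution(
            status="infeasible",
            objective=float("nan"),
            chosen=[(None, 0)] * J,
            y1=np.zeros(J),
            y2=np.zeros(J),
            z_s=np.full(S, np.nan),
            survey_spend=float("nan"),
            removal_spend=np.full(S, np.nan),
            mip_gap=0.0,
            x=np.zeros(t.K),
            var=np.zeros(t.K),
            kind=f"oracle-{problem}",
        )
    obj, ks, y1, y2, z_s, spend, removal = best
    chosen = []
    x = np.zeros(t.K)
    for j, k in enumerate(ks):
        o = data.menu.options[j][t.local[k]]
        chosen.append((o.method, o.n))
        x[k] = 1.0
    return Solution(
        status="optimal",
        objective=obj,
        chosen=chosen,
        y1=y1,
        y2=y2,
        z_s=z_s,
        survey_spend=spend,
        removal_spend=removal,
        mip_gap=0.0,
        x=x,
        var=x,
        kind=f"oracle-{problem}" + ("" if alpha is None else f"-cvar{alpha}"),
    )


def _inner_removal(t, ks, B, data, alpha=None, y_method="lp"):
    """Optimal removal fractions for a fixed survey assignment.

    Returns (objective, y1, y2, z_s, removal_spend) or None if infeasible.
    """
    J = len(ks)
    S = t.S
    spend = float(t.survey_x[ks].sum())
    if spend > B + 1e-9:
        return None
    surveyed = [j for j in range(J) if t.is_survey[ks[j]]]
    const_s = t.coef_x[:, ks].sum(axis=1)  # (S,)
    if not surveyed:
        z_s = const_s
        obj = float(z_s.mean()) if alpha is None else cvar_of(z_s, alpha)
        return obj, np.zeros(J), np.zeros(J), z_s, np.zeros(S)

    kk = np.array([ks[j] for j in surveyed])
    # columns: y1 then y2 per surveyed site
    cy = np.concatenate([t.coef_y1[:, kk], t.coef_y2[:, kk]], axis=1)  # (S, 2m)
    rm = np.concatenate([t.rm_y1[:, kk], t.rm_y2[:, kk]], axis=1)  # (S, 2m)
    cap_rows = rm
    cap_rhs = np.full(S, B - spend)
    if data.budget_removal is not None:
        cap_rows = np.vstack([cap_rows, rm])
        cap_rhs = np.concatenate([cap_rhs, np.full(S, data.budget_removal)])
    if data.budget_survey is not None and spend > data.budget_survey + 1e-9:
        return None

    if y_method == "grid" and alpha is None:
        if len(surveyed) > 1:
            raise ValueError(
                "the 0.01-step grid check enumerates a removal-fraction "
                "pair for one surveyed site; this assignment surveys "
                f"{len(surveyed)}"
            )
        grid = np.round(np.arange(0.0, 1.0 + 1e-12, 0.01), 2)
        Y = np.array(list(itertools.product(grid, grid)))  # (101^2, 2)
        feasible = np.all(cap_rows @ Y.T <= cap_rhs[:, None] + 1e-9, axis=0)
        if not feasible.any():
            return None
        objs = const_s.mean() + Y[feasible] @ cy.mean(axis=0)
        i = int(np.argmin(objs))
        obj = float(objs[i])
        y = Y[feasible][i]
    elif alpha is None:
        c = cy.mean(axis=0)
        res = linprog(
            c,
            A_ub=cap_rows,
            b_ub=cap_rhs,
            bounds=[(0.0, 1.0)] * cy.shape[1],
            method="highs",
        )
        if res.status != 0:
            return None
        y = res.x
        obj = float(const_s.mean() + res.fun)
    else:
        # variables: y (2m), eta, u_s (S)
        m2 = cy.shape[1]
        c = np.zeros(m2 + 1 + S)
        c[m2] = 1.0
        c[m2 + 1 :] = 1.0 / ((1.0 - alpha) * S)
        A = np.zeros((cap_rows.shape[0] + S, m2 + 1 + S))
        b = np.zeros(cap_rows.shape[0] + S)
        A[: cap_rows.shape[0], :m2] = cap_rows
        b[: cap_rows.shape[0]] = cap_rhs
        for s in range(S):
            r = cap_rows.shape[0] + s
            A[r, :m2] = cy[s]
            A[r, m2] = -1.0
            A[r, m2 + 1 + s] = -1.0
            b[r] = -const_s[s]
        bounds = [(0.0, 1.0)] * m2 + [(None, None)] + [(0.0, None)] * S
        res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
        if res.status != 0:
            return None
        y = res.x[:m2]
        obj = float(res.fun)

    m = len(surveyed)
    y1 = np.zeros(J)
    y2 = np.zeros(J)
    for i, j in enumerate(surveyed):
        y1[j] = y[i]
        y2[j] = y[m + i]
    z_s = const_s + cy @ y
    removal = rm @ y
    return obj, y1, y2, z_s, removal


# ---------------------------------------------------------------------------
# model export
# ---------------------------------------------------------------------------


def write_lp(model: ModelSpec, path: str | Path) -> None:
    """Export the model in CPLEX LP text format for cross-solver audit."""
    names = [f"v{i}" for i in range(model.n_var)]
    lines = ["Minimize", " obj: " + _lincomb(model.c, names), "Subject To"]
    A = model.A_ub.tocsr()
    for i in range(A.shape[0]):
        row = A.getrow(i)
        expr = _lincomb_sparse(row, names)
        label = model.labels_ub[i].replace("[", "_").replace("]", "").replace(
            "=", ""
        ).replace(",", "_")
        lines.append(f" c{i}_{label}: {expr} <= {model.b_ub[i]:.12g}")
    E = model.A_eq.tocsr()
    for i in range(E.shape[0]):
        row = E.getrow(i)
        expr = _lincomb_sparse(row, names)
        label = model.labels_eq[i].replace("[", "_").replace("]", "").replace(
            "=", ""
        ).replace(",", "_")
        lines.append(f" e{i}_{label}: {expr} = {model.b_eq[i]:.12g}")
    lines.append("Bounds")
    for i in range(model.n_var):
        lo = "-inf" if np.isneginf(model.lb[i]) else f"{model.lb[i]:.12g}"
        hi = "+inf" if np.isposinf(model.ub[i]) else f"{model.ub[i]:.12g}"
        lines.append(f" {lo} <= {names[i]} <= {hi}")
    binaries = [names[i] for i in range(model.n_var) if model.integrality[i]]
    if binaries:
        lines.append("Binaries")
        lines.append(" " + " ".join(binaries))
    lines.append("End")
    Path(path).write_text("\n".join(lines) + "\n")


def _lincomb(c: np.ndarray, names: list[str]) -> str:
    terms = []
    for i in np.flatnonzero(c):
        coef = c[i]
        sign = "+" if coef >= 0 else "-"
        terms.append(f"{sign} {abs(coef):.12g} {names[i]}")
    return " ".join(terms) if terms else "0 " + names[0]


def _lincomb_sparse(row, names: list[str]) -> str:
    terms = []
    for idx, coef in zip(row.indices, row.data):
        sign = "+" if coef >= 0 else "-"
        terms.append(f"{sign} {abs(coef):.12g} {names[idx]}")
    return " ".join(terms)
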