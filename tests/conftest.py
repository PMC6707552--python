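"""Shared fixtures: tiny randomized problem instances and the Monte-Carlo
oracle for the acceptance-sampling expectations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pestsurvey.costs import RemovalCostSpec
from pestsurvey.landscape import Landscape, ScenarioSet
from pestsurvey.optimize import (
    MenuOption,
    NONE_OPTION,
    ProblemData,
    SamplingMenu,
)


def line_landscape(J: int, hosts: np.ndarray | None = None, rng=None) -> Landscape:
    """A 1 x J strip of sites with the first cell infested."""
    if hosts is None:
        rng = rng or np.random.default_rng(0)
        hosts = rng.integers(5, 25, size=J)
    hosts = np.asarray(hosts, dtype=int)
    small = (hosts * 0.8).round().astype(int)
    sites = pd.DataFrame(
        {
            "id": np.arange(J),
            "row": np.zeros(J, dtype=int),
            "col": np.arange(J),
            "centroid_x": np.arange(J) + 0.5,
            "centroid_y": np.full(J, 0.5),
            "hosts_small": small,
            "hosts_large": hosts - small,
            "is_infested_seed": [True] + [False] * (J - 1),
            "distance_km": np.arange(J, dtype=float),
            "distance_class": np.arange(J),
        }
    )
    return Landscape(sites=sites)


def tiny_problem(
    seed: int = 0,
    J: int = 3,
    S: int = 2,
    n_options: int = 3,
    budget: float = 600.0,
    removal_cost: float = 50.0,
    budget_survey: float | None = None,
    budget_removal: float | None = None,
) -> ProblemData:
    """A randomized instance small enough for the brute-force oracle."""
    rng = np.random.default_rng(seed)
    land = line_landscape(J, rng=rng)
    gamma = rng.uniform(0.02, 0.55, size=(S, J))
    N = land.hosts
    options = []
    for j in range(J):
        opts = [NONE_OPTION]
        methods = [("trap", 0.5), ("branch", 0.7)]
        rng.shuffle(methods)
        for method, e in methods[: n_options - 1]:
            n = int(rng.integers(1, max(2, min(N[j], 8))))
            opts.append(
                MenuOption(
                    method=method,
                    n=n,
                    unit_cost=float(np.round(rng.uniform(5.0, 25.0), 2)),
                    detection_rate=e,
                )
            )
        options.append(opts)
    return ProblemData(
        landscape=land,
        scenarios=ScenarioSet(gamma=gamma, seed=seed),
        menu=SamplingMenu(options=options),
        removal_cost=RemovalCostSpec(unit_cost=removal_cost),
        budget_total=budget,
        budget_survey=budget_survey,
        budget_removal=budget_removal,
    )


def mc_site_expectations(
    gamma: float, e: float, n: int, N: int, reps: int, seed: int = 0
):
    """Monte-Carlo estimates of (P, E, F) with standard errors.

    Simulates Bernoulli infestation of every tree and Bernoulli detection
    of each infested tree in the sample; accumulates the total infested
    count against the detection event.
    """
    rng = np.random.default_rng(seed)
    k_in = rng.binomial(n, gamma, size=reps)
    k_out = rng.binomial(N - n, gamma, size=reps)
    detected = rng.binomial(k_in, e) > 0
    total = k_in + k_out
    nodetect = ~detected
    P_hat = nodetect.mean()
    E_draws = total * nodetect
    F_draws = total * detected
    # floor the standard errors at the resolution of the estimator (one
    # event, or one tree-count, over the number of replicates): with zero
    # observed events the sample s.e. collapses to 0 even though values up
    # to ~1/reps remain consistent with the data
    return {
        "P": (P_hat, max(np.sqrt(P_hat * (1 - P_hat) / reps), 1.0 / reps)),
        "E": (E_draws.mean(), max(E_draws.std(ddof=1) / np.sqrt(reps), N / reps)),
        "F": (F_draws.mean(), max(F_draws.std(ddof=1) / np.sqrt(reps), N / reps)),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
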