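# pestsurvey

Optimal allocation of invasive-pest detection surveys — with optional
host-tree removal — across an urban landscape, under uncertainty about
where the pest has spread. The package was built around the emerald ash
borer (EAB, *Agrilus planipennis*), a wood-boring beetle that kills North
American ash (*Fraxinus*) and is typically managed, after detection, by
removing infested and susceptible host trees. It is intended for
quantitative ecologists and forest-health program planners who need to
split a fixed budget between inspecting trees and removing them.

## The model

The survey area is a grid of 1×1-km sites. Site *j* holds *N<sub>j</sub>*
host trees, each infested with probability γ<sub>js</sub> under infestation
scenario *s* (scenarios capture uncertainty about spread; their per-site
means decay with distance from the known infested core). A site is treated
as a *lot* in an acceptance-sampling plan: inspect *n<sub>jm</sub>* trees
with a method whose per-tree detection rate is *e* (0.7 for destructive
branch sampling, 0.5 for baited traps), and declare the site infested on
any positive.

For one site the calculus gives, with P = (1 − γe)<sup>n</sup> and
β = (1 − e)/(1 − γe):

- expected **slippage** (infested trees missed when the site is declared
  clean): E = Pγ(N − n) + nγPβ;
- expected infested trees present **given detection**:
  F = γ(N − n)(1 − P) + nγ(1 − Pβ), with E + F = γN always;
- after removing fractions y₁ (sampled) and y₂ (unsampled) of trees
  following a detection, the residual
  γ(N − n)(1 − P)(1 − y₂) + nγ(1 − Pβ)(1 − y₁).

A mixed-integer program picks one sampling option per site (binary
x<sub>jm</sub>) and removal fractions y₁, y₂ ∈ [0, 1] to minimize the
scenario-averaged expected number of infested trees remaining, subject to
a budget on survey spending plus *expected* removal spending in every
scenario, y ≤ x linking, and one option per site. Variants: two
survey-only delimiting objectives (minimize expected undetected-infested
sites, or expected slippage), a two-stage fix-the-surveys-then-optimize-
removal re-solve, split survey/removal budgets, and an ambiguity-averse
objective minimizing CVaR<sub>α</sub> of the per-scenario outcome via the
standard linearization. Models are solved with the HiGHS branch-and-bound
solver (`scipy.optimize.milp`); a brute-force oracle audits small
instances.

No real tree inventory ships with the package: a synthetic-landscape
module generates gridded host densities and distance-decay infestation
scenarios with the same statistical structure.

## Worked example

```python
import dataclasses
import pestsurvey as ps

cfg = ps.RunConfig()                # 8x8-km city, 200 scenarios
data = ps.build_problem(cfg)
d = dataclasses.replace(data, budget_total=200_000.0)

sol = ps.solve(ps.build_survey_removal(d), mip_rel_gap=1e-3)
print(sol.status, round(sol.objective, 2))
print(round(sol.survey_spend, 2), round(100 * sol.survey_spend / 2e5, 2))
print(round(ps.expected_removed_infested(sol, d.scenarios, d), 2))
```

prints

```
optimal 503.08
10394.21 5.2
112.89
```

meaning: the optimal plan leaves an expected 503.1 infested trees in the
landscape, spends only $10,394 (5.2% of the $200k budget) on surveys —
removal is far more expensive per tree than inspection, so most of the
budget is reserved for it — and removes an expected 112.9 infested trees.
Survey-only plans re-solved for removal afterwards remove fewer (106.2 and
100.8 for the two delimiting objectives at the same survey spend), which
is the core argument for planning surveys and removal jointly.

A CLI wraps the same library:

```sh
pestsurvey generate --config cfg.json --out runs/demo
pestsurvey solve --config cfg.json --out runs/demo --export-lp
pestsurvey compare --config cfg.json --budgets 100000,200000,400000
pestsurvey sensitivity --config cfg.json
```

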