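# Methods

## Acceptance-sampling calculus

Each survey site is a lot of *N* host trees; trees are infested i.i.d.
with probability γ, and inspecting an infested tree detects it with
probability *e* (the method's detection rate). Inspecting *n* trees and
declaring the site infested on any positive gives a non-detection
probability P = (1 − γe)ⁿ. Conditional on non-detection the expected
infested count in the sample shrinks by the factor β = (1 − e)/(1 − γe);
the expected slippage is E = Pγ(N − n) + nγPβ, the expected infested
count given detection is F = γ(N − n)(1 − P) + nγ(1 − Pβ), and
E + F = γN holds identically (conditioning on the detection event cannot
change the unconditional mean — the package treats this as a hard
invariant at 1e-9). Removing fractions y₁ of the sampled and y₂ of the
unsampled population after a detection leaves the residual
γ(N − n)(1 − P)(1 − y₂) + nγ(1 − Pβ)(1 − y₁), linear in (y₁, y₂).

Numerics: powers are evaluated as exp(n·log1p(−γe)) so sample sizes in the
hundreds cannot underflow, and the degenerate case γe = 1 (certain
infestation, perfect detection) takes the limit value Pβ → 0 for n ≥ 1;
the stand-alone adjustment factor β raises a domain error there because
the conditioning event has probability zero. Sample sizes are integers —
the optimizer's menu is discrete, so fractional n is rejected rather than
interpolated.

## Optimization models

Decision variables: one binary x<sub>jm</sub> per site and menu option
(method × sample size, plus a mandatory no-survey option) and continuous
removal fractions y₁<sub>jm</sub>, y₂<sub>jm</sub> ∈ [0, 1] per survey
option. The joint objective averages, over S infestation scenarios, the
sum over sites of slippage plus post-removal residual. Constraints:

- exactly one option per site (Σ<sub>m</sub> x<sub>jm</sub> = 1);
- tight linking y ≤ x (removal requires a survey; this dominates the
  looser y ≤ x·n form and leaves the feasible set unchanged given the
  [0, 1] bounds);
- for **every** scenario s: survey spend + expected removal spend ≤ B,
  where expected removal spend carries the detection probability
  (1 − P<sub>jms</sub>) — removal happens only after a detection;
- optional separate survey and removal caps (split-budget runs).

Survey-only problem 1 minimizes Σ x·P (expected sites with undetected
infestations); problem 2 minimizes Σ x·E (expected slippage); both only
constrain survey spending. The two-stage variant freezes x from a
survey-only solution and re-optimizes y under the joint objective — an LP.

The ambiguity-averse variant minimizes CVaR_α of the per-scenario
objective z_s via the Rockafellar–Uryasev linearization: minimize
η + (1/((1−α)S))·Σ u_s with u_s ≥ z_s − η, u_s ≥ 0, keeping all original
constraints. α defaults to 0.9 and is configurable; α = 0 reproduces the
expected-value problem exactly.

Models are solved with HiGHS branch-and-bound through
`scipy.optimize.milp`. The default relative MIP gap is 1e-4; the large
qualitative comparison runs use 1e-3 with a per-solve time limit, which
bounds the objective error at a fraction of a tree on the synthetic city
while keeping full comparisons to a couple of minutes. Tie-breaking among
equally good plans is left to the solver; the tested quantity is the
objective value, not the argmin. A brute-force oracle (exhaustive survey
assignments; inner LP, or a 0.01-step grid for a single surveyed site,
over removal fractions) verifies small instances, and models export to
CPLEX LP text format for cross-solver audit.

A structural note: because E + F = γN, every option's objective
coefficient on x equals γN — surveying by itself removes nothing, it only
*enables* removal through the linking and budget constraints. This makes
the MILP's LP relaxation fairly degenerate, which is why gap tolerance,
not instance size, drives solve time.

## Synthetic landscape and scenarios

The generator emulates the structure of an early urban EAB infestation:

- a grid of 1×1-km sites; host counts per cell are log-normal
  (median 120 trees, σ_log 0.9 by default) with optional high-density
  "river corridor" column stripes, split into two size classes (80%
  20–60 cm dbh, 20% >60 cm) matching the survey cost classes — survey
  protocols target trees above 20 cm dbh only;
- one or more known-infested seed cells; every site gets the Euclidean
  centroid distance to the nearest seed and a half-open 1-km distance
  class ⌊d⌋ (the distance metric is a modelling choice; Euclidean is the
  least surprising);
- per-tree infestation probabilities are drawn per site and scenario from
  a Beta distribution with distance-class mean
  μ_d = max(floor, μ₀·e^(−λd)) and concentration κ (defaults μ₀ = 0.3,
  λ = 0.35 /km, κ = 6, floor = 0.002). The defaults put ~30% infestation
  probability at the core decaying to near zero by ~15 km, comparable to
  what a six-year-old urban infestation looks like, with substantial
  scenario-to-scenario spread (κ = 6 gives a coefficient of variation
  near 0.6 at the core).

This parametric stand-in preserves the two features the optimizer
consumes — a decaying mean and within-class spread — but not features of
real inventories: no spatial autocorrelation of host density beyond the
corridor stripes, no correlation of γ draws across sites within a
scenario (jump-dispersal events would induce one), and no mechanistic
population dynamics. Passing tests therefore validate the calculus and
the optimization, not any claim about a particular city.

## Costs

Survey costs are component-based, in CAD, rounded half-up to cents at the
component-sum level. A two-person contractor crew at $25/h services traps
over three visits (15 min work + 10 min site access per visit); small
trees take one trap ($24.71), large trees two. That reconstruction gives
the $87.21 per-tree small-tree trapping default exactly. The remaining
defaults (trap large $124.42; branch sampling $128.90/$249.60) are
published program totals used as configured constants — their printed
component lists do not reconcile to the cent, so the totals are treated
as authoritative. Woodlot access doubles the access/setup labor via a
multiplier. The per-site cost handed to the optimizer is the
host-composition-weighted mean of the two class costs.

Removal cost defaults to $400 per tree — a configurable working
assumption for urban ash removal and disposal; the qualitative results
require only that removal is an order of magnitude costlier than
inspection.

## Study conditions used in tests and the acceptance script

The fixed-seed synthetic city is an 8×8-km grid with S = 200 scenarios
and budgets of $100k/$200k/$400k — the same grid-to-budget ratio regime
as a mid-size city program (roughly $1.5k–6k per km²), small enough that
a full joint/survey-only/CVaR comparison solves in minutes on one CPU.
Tiny randomized instances (≤4 sites, ≤3 options, ≤10 scenarios) are used
wherever exhaustive enumeration serves as the oracle. Monte-Carlo checks
of the site calculus use 10⁶ replicates and a 3-standard-error band, with
the standard error floored at the estimator's resolution (one event or
one tree-count per replicate set) to handle rare-event cells where the
sample variance collapses to zero.

## Sensitivity analysis

Each named parameter (survey cost, detection rate, host density,
infestation rate, removal cost) is rescaled globally by ±20%, the problem
is re-solved, and each output's sensitivity is |relative output change| /
0.20, averaged over the two directions (the aggregation is recorded in
the run metadata; one-sided ratios are also derivable from it). Host
density perturbation rescales N_j and drops menu options exceeding the
new N_j; infestation-rate perturbation rescales all γ with clipping at 1.
Infeasible re-solves leave missing cells rather than failing the table.

## Known limitations

- Removal decisions are single-stage and scenario-independent, matching
  the planning problem; there is no temporal dynamics, chemical-treatment
  option, or multi-year budget.
- The per-scenario budget constraint uses *expected* removal spending;
  realized removal costs in any one outcome can exceed it.
- Scenario independence across sites understates spatially correlated
  spread, so the value of accounting for uncertainty is, if anything,
  conservative here.
- HiGHS determinism holds for a fixed environment; across BLAS/solver
  builds the argmin may differ among near-ties even though objective
  values agree to the gap tolerance.
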