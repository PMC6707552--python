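"""Component-based per-tree survey costs and removal costs.

Two inspection methods are modelled for the emerald ash borer case:

* **trapping** — a baited sticky trap hung in the tree, serviced over
  three visits (setup, sampling, teardown) by a two-person crew; cheaper
  per tree but with a lower detection rate (0.5 per trap);
* **branch sampling** — destructive dissection of mid-crown branches; a
  single visit but with bark peeling and branch disposal labor; more
  expensive with a higher detection rate (0.7).

Trees are costed by size class: "small" (20-60 cm dbh) trees need one trap
or two branches, "large" (>60 cm dbh) trees twice the effort. The default
per-tree unit costs below are the published program totals for a 2018
Winnipeg survey campaign (CAD); the component calculator reproduces the
small-tree trapping total exactly from its parts (trap price + crew labor),
and is provided for auditability of the other defaults, whose printed
totals include components not fully itemized.

Money is handled in CAD, rounded half-up to cents at the component-sum
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "SMALL",
    "LARGE",
    "TRAP",
    "BRANCH",
    "DEFAULT_UNIT_COSTS",
    "DEFAULT_DETECTION_RATES",
    "DEFAULT_TRAP_UNIT_PRICE",
    "LaborSpec",
    "MethodCostSpec",
    "RemovalCostSpec",
    "labor_cost",
    "trap_survey_unit_cost",
    "site_weighted_unit_cost",
]

SMALL = "small"  # 20-60 cm dbh
LARGE = "large"  # >60 cm dbh
TRAP = "trap"
BRANCH = "branch"

#: Published per-tree survey totals (CAD) by (method, size class).
DEFAULT_UNIT_COSTS: dict[tuple[str, str], float] = {
    (TRAP, SMALL): 87.21,
    (TRAP, LARGE): 124.42,
    (BRANCH, SMALL): 128.90,
    (BRANCH, LARGE): 249.60,
}

#: Detection rate per inspected tree by method.
DEFAULT_DETECTION_RATES: dict[str, float] = {BRANCH: 0.7, TRAP: 0.5}

#: Price of one baited trap, CAD.
DEFAULT_TRAP_UNIT_PRICE = 24.71

#: Traps (or branch-pair multiples) required per tree by size class.
TRAPS_REQUIRED = {SMALL: 1, LARGE: 2}


def _round_cents(amount: float) -> float:
    return float(
        Decimal(repr(float(amount))).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class LaborSpec:
    """Contractor crew: hourly rate per person (CAD) and crew size."""

    hourly_rate: float = 25.0
    crew_size: int = 2

    def __post_init__(self) -> None:
        if self.hourly_rate <= 0:
            raise ValueError("hourly_rate must be positive")
        if self.crew_size < 1:
            raise ValueError("crew_size must be >= 1")


@dataclass(frozen=True)
class MethodCostSpec:
    """Per-tree survey cost and detection rate for one method/size class."""

    method: str
    size_class: str
    unit_cost: float
    detection_rate: float
    woodlot_access_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in (TRAP, BRANCH):
            raise ValueError(f"unknown method {self.method!r}")
        if self.size_class not in (SMALL, LARGE):
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.unit_cost <= 0:
            raise ValueError("unit_cost must be positive")
        if not 0.0 < self.detection_rate <= 1.0:
            raise ValueError("detection_rate must be in (0, 1]")
        if self.woodlot_access_multiplier < 1.0:
            raise ValueError("woodlot_access_multiplier must be >= 1")


@dataclass(frozen=True)
class RemovalCostSpec:
    """Cost of removing one tree (CAD).

    The default of 400 CAD/tree is a configurable working assumption for
    urban ash removal and disposal; the analyses here only require that
    removal is much more expensive per tree than surveying.
    """

    unit_cost: float = 400.0

    def __post_init__(self) -> None:
        if self.unit_cost <= 0:
            raise ValueError("removal unit_cost must be positive")


def labor_cost(person_minutes: float, labor: LaborSpec) -> float:
    """Crew labor cost in CAD for a total of ``person_minutes`` of work,
    rounded half-up to cents."""
    if person_minutes < 0:
        raise ValueError("person_minutes must be >= 0")
    return _round_cents(person_minutes / 60.0 * labor.hourly_rate)


def trap_survey_unit_cost(
    size_class: str,
    labor: LaborSpec | None = None,
    trap_unit_price: float = DEFAULT_TRAP_UNIT_PRICE,
    visits: int = 3,
    work_min_per_visit: float = 15.0,
    access_min_per_visit: float = 10.0,
    woodlot_access_multiplier: float = 1.0,
) -> float:
    """Per-tree trapping cost assembled from its components.

    One trap per small tree, two per large tree; each of the ``visits``
    site visits costs the whole crew ``work_min_per_visit`` minutes of trap
    work plus ``access_min_per_visit`` minutes of site access (access and
    setup time is multiplied for hard-to-reach woodlot trees). Rounding to
    cents happens once, on the component sum.
    """
    if size_class not in TRAPS_REQUIRED:
        raise ValueError(f"unknown size class {size_class!r}")
    if trap_unit_price < 0 or visits < 0 or work_min_per_visit < 0:
        raise ValueError("cost components must be nonnegative")
    if access_min_per_visit < 0:
        raise ValueError("cost components must be nonnegative")
    labor = labor or LaborSpec()
    minutes_per_visit = (
        work_min_per_visit + access_min_per_visit
    ) * woodlot_access_multiplier
    person_minutes = visits * minutes_per_visit * labor.crew_size
    traps = TRAPS_REQUIRED[size_class]
    total = traps * trap_unit_price + person_minutes / 60.0 * labor.hourly_rate
    return _round_cents(total)


def site_weighted_unit_cost(
    hosts_small: int,
    hosts_large: int,
    unit_cost_small: float,
    unit_cost_large: float,
) -> float:
    """Host-composition-weighted mean per-tree survey cost for a site.

    The site-level optimizer uses a single per-tree cost per site and
    method; sites with a mix of size classes get the host-weighted mean of
    the two class costs.
    """
    total = hosts_small + hosts_large
    if total < 1:
        raise ValueError("site has no host trees to cost")
    if hosts_small < 0 or hosts_large < 0:
        raise ValueError("host counts must be nonnegative")
    w = (hosts_small * unit_cost_small + hosts_large * unit_cost_large) / total
    return _round_cents(w)
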