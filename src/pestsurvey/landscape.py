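"""Synthetic urban landscape and distance-decay infestation scenarios.

The generator emulates the statistical structure of an early urban
infestation of a wood-boring pest (the motivating system is emerald ash
borer in a prairie city): a 1x1-km grid of survey sites, heterogeneous host
density with optional high-density "river corridor" stripes, one or more
known-infested seed cells, and per-tree infestation probabilities that
decay with distance from the nearest infested cell.

Scenario sampling is parametric: for a site in 1-km distance class ``d``
the per-tree infestation probability is drawn from a Beta distribution with
mean ``max(gamma_floor, mu0 * exp(-lambda * d))`` and concentration
``kappa``, independently across sites and scenarios. This preserves the
two features the downstream optimization consumes — a mean that decays
with distance and within-class spread across scenarios — without claiming
any mechanistic spread model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SITE_COLUMNS",
    "HostDensitySpec",
    "DecayModel",
    "Landscape",
    "ScenarioSet",
    "make_landscape",
    "distance_to_infested",
    "sample_scenarios",
    "mean_scenario",
]

#: Column order of the site table.
SITE_COLUMNS = [
    "id",
    "row",
    "col",
    "centroid_x",
    "centroid_y",
    "hosts_small",
    "hosts_large",
    "is_infested_seed",
    "distance_km",
    "distance_class",
]


@dataclass(frozen=True)
class HostDensitySpec:
    """Log-normal host-density field with optional corridor stripes.

    ``median`` is the median trees per cell; ``sigma_log`` the log-scale
    standard deviation; cells whose column index is in ``corridor_cols``
    have their density multiplied by ``corridor_multiplier`` (a stand-in
    for riparian corridors where ash density is much higher).
    """

    median: float = 120.0
    sigma_log: float = 0.9
    corridor_cols: tuple[int, ...] = ()
    corridor_multiplier: float = 4.0

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median host density must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.corridor_multiplier <= 0:
            raise ValueError("corridor_multiplier must be positive")


@dataclass(frozen=True)
class DecayModel:
    """Distance-decay model for mean per-tree infestation probability.

    The mean at 1-km distance class ``d`` is
    ``mu_d = max(gamma_floor, mu0 * exp(-lam * d))`` and draws are
    Beta(mu_d * kappa, (1 - mu_d) * kappa): ``kappa`` controls the
    within-class spread across scenarios (larger = tighter).
    """

    mu0: float = 0.3
    lam: float = 0.35
    kappa: float = 6.0
    gamma_floor: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 < self.mu0 <= 1.0:
            raise ValueError("mu0 must be in (0, 1]")
        if self.lam < 0:
            raise ValueError("decay rate lambda must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.gamma_floor <= self.mu0:
            raise ValueError("gamma_floor must be in [0, mu0]")

    def class_mean(self, distance_class) -> np.ndarray:
        """Mean infestation probability for one or more distance classes."""
        d = np.asarray(distance_class, dtype=float)
        return np.maximum(self.gamma_floor, self.mu0 * np.exp(-self.lam * d))


@dataclass
class Landscape:
    """A grid of 1x1-km survey sites held as a pandas DataFrame."""

    sites: pd.DataFrame
    cell_size_km: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"site table is missing columns {missing}")
        ids = self.sites["id"].to_numpy()
        if len(np.unique(ids)) != len(ids) or not np.array_equal(
            np.sort(ids), np.arange(len(ids))
        ):
            raise ValueError("site ids must be unique and contiguous from 0")
        if not bool(self.sites["is_infested_seed"].any()):
            raise ValueError("landscape must contain at least one infested seed cell")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def hosts(self) -> np.ndarray:
        """Total host trees N_j per site, in site order."""
        return (
            self.sites["hosts_small"].to_numpy() + self.sites["hosts_large"].to_numpy()
        )

    def to_csv(self, path: str | Path) -> None:
        self.sites.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Landscape":
        return cls(sites=pd.read_csv(path))

    def to_geojson(self, path: str | Path) -> None:
        """Write square cell polygons with site fields as properties."""
        import json

        half = self.cell_size_km / 2.0
        features = []
        for rec in self.sites.to_dict("records"):
            cx, cy = rec["centroid_x"], rec["centroid_y"]
            ring = [
                [cx - half, cy - half],
                [cx + half, cy - half],
                [cx + half, cy + half],
                [cx - half, cy + half],
                [cx - half, cy - half],
            ]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {k: _jsonable(v) for k, v in rec.items()},
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


@dataclass
class ScenarioSet:
    """S x J matrix of per-tree infestation probabilities.

    Columns follow the site order of the landscape the set was drawn for;
    ``seed`` records the RNG seed used (None for derived sets such as the
    scenario mean).
    """

    gamma: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if self.gamma.ndim != 2 or self.gamma.shape[0] < 1:
            raise ValueError("gamma must be an S x J matrix with S >= 1")
        if np.any(~np.isfinite(self.gamma)):
            raise ValueError("gamma contains non-finite entries")
        if np.any(self.gamma < 0) or np.any(self.gamma > 1):
            raise ValueError("gamma entries must lie in [0, 1]")

    @property
    def n_scenarios(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_sites(self) -> int:
        return self.gamma.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.gamma, columns=[f"site_{j}" for j in range(self.n_sites)]
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int | None = None) -> "ScenarioSet":
        return cls(gamma=pd.read_csv(path).to_numpy(dtype=float), seed=seed)


def make_landscape(
    n_rows: int,
    n_cols: int,
    host_density_spec: HostDensitySpec | None = None,
    seed_cells: Sequence[tuple[int, int]] = ((0, 0),),
    size_mix: tuple[float, float] = (0.8, 0.2),
    rng_seed: int = 0,
) -> Landscape:
    """Generate a synthetic grid landscape.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; sites are 1x1-km cells with centroids at
        ``(col + 0.5, row + 0.5)`` km.
    host_density_spec : HostDensitySpec
        Log-normal density field parameters (defaults emulate a
        heterogeneous urban ash inventory).
    seed_cells : sequence of (row, col)
        Known infested cells; distances are measured to the nearest one.
    size_mix : (small_fraction, large_fraction)
        Expected fractions of 20-60 cm and >60 cm dbh trees; must sum to 1.
    rng_seed : int
        Seed for the host-count draws; fixed seed gives an identical
        landscape.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must contain at least one cell")
    if len(seed_cells) == 0:
        raise ValueError("seed_cells must not be empty")
    for r, c in seed_cells:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"seed cell {(r, c)} lies outside the grid")
    if abs(sum(size_mix) - 1.0) > 1e-9 or any(f < 0 for f in size_mix):
        raise ValueError("size_mix fractions must be nonnegative and sum to 1")
    spec = host_density_spec or HostDensitySpec()

    rng = np.random.default_rng(rng_seed)
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    mu_log = np.log(spec.median)
    density = rng.lognormal(mean=mu_log, sigma=spec.sigma_log, size=rows.size)
    if spec.corridor_cols:
        in_corridor = np.isin(cols, np.asarray(spec.corridor_cols))
        density = np.where(in_corridor, density * spec.corridor_multiplier, density)
    hosts = np.round(density).astype(int)
    hosts_small = rng.binomial(hosts, size_mix[0])
    hosts_large = hosts - hosts_small

    seed_mask = np.zeros(rows.size, dtype=bool)
    for r, c in seed_cells:
        seed_mask[r * n_cols + c] = True

    sites = pd.DataFrame(
        {
            "id": np.arange(rows.size),
            "row": rows,
            "col": cols,
            "centroid_x": cols + 0.5,
            "centroid_y": rows + 0.5,
            "hosts_small": hosts_small,
            "hosts_large": hosts_large,
            "is_infested_seed": seed_mask,
            "distance_km": 0.0,
            "distance_class": 0,
        }
    )
    landscape = Landscape(sites=sites)
    distance_to_infested(landscape, inplace=True)
    return landscape


def distance_to_infested(
    landscape: Landscape, inplace: bool = False
) -> pd.DataFrame:
    """Euclidean centroid distance to the nearest infested seed cell.

    Returns a DataFrame with columns ``distance_km`` and ``distance_class``
    (half-open 1-km bins ``[d, d+1)``, i.e. ``floor(distance)``); with
    ``inplace=True`` the landscape's site table is updated as well.
    """
    sites = landscape.sites
    seeds = sites[sites["is_infested_seed"]]
    if len(seeds) == 0:
        raise ValueError("landscape has no infested seed cells")
    xy = sites[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    seed_xy = seeds[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    diff = xy[:, None, :] - seed_xy[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    dclass = np.floor(dist).astype(int)
    out = pd.DataFrame({"distance_km": dist, "distance_class": dclass})
    if inplace:
        sites["distance_km"] = dist
        sites["distance_class"] = dclass
    return out


def sample_scenarios(
    landscape: Landscape,
    decay: DecayModel,
    S: int,
    rng_seed: int = 0,
) -> ScenarioSet:
    """Draw ``S`` infestation scenarios for a landscape.

    Each scenario is a vector of per-tree infestation probabilities, one
    per site, drawn independently (across sites and scenarios) from the
    distance-class Beta distribution of the decay model. Seed cells use
    distance class 0. Deterministic for a fixed ``rng_seed``.
    """
    if S < 1:
        raise ValueError("need at least one scenario")
    rng = np.random.default_rng(rng_seed)
    dclass = landscape.sites["distance_class"].to_numpy()
    mu = decay.class_mean(dclass)  # (J,)
    a = mu * decay.kappa
    b = (1.0 - mu) * decay.kappa
    # beta() requires strictly positive shape parameters; mu == 1 gives b == 0
    # (point mass at 1), handled explicitly
    gamma = np.empty((S, landscape.n_sites))
    degenerate = b <= 0
    ok = ~degenerate
    gamma[:, ok] = rng.beta(a[ok], b[ok], size=(S, int(ok.sum())))
    gamma[:, degenerate] = 1.0
    return ScenarioSet(gamma=gamma, seed=rng_seed)


def mean_scenario(scenarios: ScenarioSet) -> ScenarioSet:
    """Collapse a scenario set to its per-site mean (an S = 1 set).

    This is the "no uncertainty" counterpart used to measure the effect of
    scenario spread on the optimal plan.
    """
    return ScenarioSet(gamma=scenarios.gamma.mean(axis=0, keepdims=True), seed=None)
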