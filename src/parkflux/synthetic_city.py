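"""Seedable synthetic city generator and fixed test fixtures.

Generates grid tracts with Dirichlet demographic mixtures, log-normally sized
parks (evenly spread or spatially clustered), and simple home/other daily
trajectories with Poisson activity counts and exponential-tailed
displacements snapped to a 400 m grid.  It reproduces the statistical shapes
the analysis pipeline consumes — it is not a mechanistic mobility model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from shapely.geometry import Point, box

from .exposure import Activity, ExposureNetwork, Trajectory
from .geo_core import GROUP_ORDER, Park, Tract

SNAP_GRID_M = 400.0
JITTER_M = 200.0


@dataclass
class SyntheticCityConfig:
    grid_rows: int = 4
    grid_cols: int = 4
    tract_side_m: float = 2000.0
    n_parks: int = 10
    park_area_mu_log: float = -3.0   # ln of km^2; exp(-3) ~ 0.05 km^2
    park_area_sigma_log: float = 0.8
    park_placement: str = "even"     # "even" | "clustered"
    n_agents: int = 200
    mean_other_activities: float = 3.0
    displacement_scale_km: float = 2.0
    segregation_alpha: float = 1.0
    population_per_tract: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_rows, self.grid_cols, self.n_parks, self.n_agents) <= 0:
            raise ValueError("all counts must be positive")
        if self.tract_side_m <= 0 or self.segregation_alpha <= 0:
            raise ValueError("tract_side_m and segregation_alpha must be positive")
        if self.park_placement not in ("even", "clustered"):
            raise ValueError("park_placement must be 'even' or 'clustered'")


def generate_city(config: SyntheticCityConfig) -> tuple[list[Tract], list[Park]]:
    """Grid tracts with Dirichlet group mixtures plus log-normal parks."""
    rng = np.random.default_rng(config.seed)
    side = config.tract_side_m
    width = config.grid_cols * side
    height = config.grid_rows * side

    # global mixture the Dirichlet is centered on
    base = np.array([0.45, 0.2, 0.1, 0.2, 0.05])
    tracts = []
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            probs = rng.dirichlet(config.segregation_alpha * base)
            counts = rng.multinomial(config.population_per_tract, probs)
            tracts.append(Tract(
                tract_id=f"T{r:03d}{c:03d}",
                region=box(c * side, r * side, (c + 1) * side, (r + 1) * side),
                group_counts=dict(zip(GROUP_ORDER, (int(x) for x in counts))),
            ))

    if config.park_placement == "even":
        cx = rng.uniform(0, width, config.n_parks)
        cy = rng.uniform(0, height, config.n_parks)
    else:  # clustered around a single hotspot
        hot = np.array([rng.uniform(0, width), rng.uniform(0, height)])
        spread = min(width, height) / 10.0
        cx = np.clip(hot[0] + rng.normal(0, spread, config.n_parks), 0, width)
        cy = np.clip(hot[1] + rng.normal(0, spread, config.n_parks), 0, height)

    areas_km2 = rng.lognormal(config.park_area_mu_log, config.park_area_sigma_log,
                              config.n_parks)
    parks = []
    for k in range(config.n_parks):
        half = math.sqrt(areas_km2[k] * 1e6) / 2.0  # square park
        parks.append(Park(
            park_id=f"P{k:04d}",
            region=box(cx[k] - half, cy[k] - half, cx[k] + half, cy[k] + half),
        ))
    return tracts, parks


def _uniform_point_in(region, rng: np.random.Generator) -> tuple[float, float]:
    minx, miny, maxx, maxy = region.bounds
    for _ in range(10_000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if region.covers(Point(x, y)):
            return x, y
    raise RuntimeError("rejection sampling failed: degenerate region?")


def generate_trajectories(config: SyntheticCityConfig,
                          tracts: list[Tract]) -> list[Trajectory]:
    """Homes proportional to tract population; Poisson other-activity counts;
    isotropic exponential displacements snapped to the 400 m grid then
    jittered by at most 200 m."""
    rng = np.random.default_rng(config.seed + 1)
    pops = np.array([t.population for t in tracts], dtype=float)
    if pops.sum() == 0:
        pops = np.ones(len(tracts))
    probs = pops / pops.sum()
    home_tract = rng.choice(len(tracts), size=config.n_agents, p=probs)

    trajectories = []
    for a in range(config.n_agents):
        t = tracts[home_tract[a]]
        hx, hy = _uniform_point_in(t.region, rng)
        agent = f"A{a:06d}"
        home = Activity(agent, "home", hx, hy)
        n_o = rng.poisson(config.mean_other_activities)
        others = []
        for q in range(n_o):
            radius = rng.exponential(config.displacement_scale_km * 1000.0)
            theta = rng.uniform(0, 2 * math.pi)
            x = hx + radius * math.cos(theta)
            y = hy + radius * math.sin(theta)
            x = round(x / SNAP_GRID_M) * SNAP_GRID_M + rng.uniform(-JITTER_M, JITTER_M)
            y = round(y / SNAP_GRID_M) * SNAP_GRID_M + rng.uniform(-JITTER_M, JITTER_M)
            others.append(Activity(agent, "other", x, y, slot=q))
        trajectories.append(Trajectory(agent, home, tuple(others)))
    return trajectories


def fig4_fixture() -> tuple[list[Tract], list[Park], list[Trajectory]]:
    """Worked network-construction example: one tract, three parks, two
    trajectories.

    Coordinates keep >= 50 m of margin around the 200 m exposure threshold so
    float error cannot flip any exposure:

    * u1: two other-activities; only the second (150 m from park A) is exposed,
      and only to park A.
    * u2: four other-activities; the first and third share one far-away point,
      the second (100 m from all three parks) is exposed to every park, the
      fourth (100 m from park C) only to park C.

    build_incidence at radius 200 yields X = [2, 1, 2].
    """
    tract = Tract("t1", box(0, 0, 3000, 3000),
                  {"White": 50, "Black": 20, "Asian": 10, "Hispanic": 20, "Other": 0})
    parks = [
        Park("p1", box(1700, 1900, 1900, 2100)),  # west of center point
        Park("p2", box(2100, 1900, 2300, 2100)),  # east
        Park("p3", box(1900, 1700, 2100, 1900)),  # south
    ]
    far = (500.0, 500.0)  # > 1 km from every park
    u1 = Trajectory("u1", Activity("u1", "home", 600, 2500), (
        Activity("u1", "other", *far, slot=0),
        Activity("u1", "other", 1550, 2000, slot=1),   # 150 m from p1 only
    ))
    u2 = Trajectory("u2", Activity("u2", "home", 2500, 600), (
        Activity("u2", "other", *far, slot=0),
        Activity("u2", "other", 2000, 2000, slot=1),   # 100 m from p1, p2, p3
        Activity("u2", "other", *far, slot=2),         # same point as slot 0
        Activity("u2", "other", 2000, 1600, slot=3),   # 100 m from p3 only
    ))
    return [tract], parks, [u1, u2]


def planted_partition_incidence(k_blocks: int, tracts_per_block: int,
                                parks_per_block: int, within_weight: float,
                                between_weight: float, seed: int = 0,
                                ) -> tuple[ExposureNetwork, np.ndarray, np.ndarray]:
    """Block-structured Poisson incidence for community-detection tests.

    Returns the network plus the planted block id of each tract and park.
    between_weight=0 gives disconnected blocks.
    """
    rng = np.random.default_rng(seed)
    nT = k_blocks * tracts_per_block
    nP = k_blocks * parks_per_block
    tract_block = np.repeat(np.arange(k_blocks), tracts_per_block)
    park_block = np.repeat(np.arange(k_blocks), parks_per_block)
    lam = np.where(tract_block[:, None] == park_block[None, :],
                   within_weight, between_weight)
    X = rng.poisson(lam)
    net = ExposureNetwork(
        X=sp.csr_matrix(X),
        tract_ids=[f"T{i}" for i in range(nT)],
        park_ids=[f"P{j}" for j in range(nP)],
    )
    return net, tract_block, park_block
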