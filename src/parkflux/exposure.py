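"""Bipartite tract-park incidence network built from daily trajectories.

Each *other*-type activity exposes its agent to every park within the
exposure radius (default 200 m) of the activity point; the exposure is
credited to the census tract containing the agent's home.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from shapely.geometry import Point
from shapely.strtree import STRtree

from .geo_core import Park, Tract, TractIndex

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_M = 200.0


@dataclass(frozen=True)
class Activity:
    agent_id: str
    kind: str  # "home" or "other"
    x: float
    y: float
    slot: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("home", "other"):
            raise ValueError(f"activity kind must be 'home' or 'other', got {self.kind!r}")

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass(frozen=True)
class Trajectory:
    """One agent-day: a single home plus an ordered list of other-activities.

    Repeated identical other locations are legitimate and counted separately.
    """

    agent_id: str
    home: Activity
    others: tuple[Activity, ...] = ()

    def __post_init__(self) -> None:
        if self.home.kind != "home":
            raise ValueError("home activity must have kind='home'")
        for a in self.others:
            if a.kind != "other":
                raise ValueError("non-home activities must have kind='other'")

    @property
    def n_other(self) -> int:
        return len(self.others)


@dataclass
class ExposureNetwork:
    """Sparse integer incidence: rows are tracts, columns are parks."""

    X: sp.csr_matrix
    tract_ids: list[str]
    park_ids: list[str]
    radius_m: float = DEFAULT_RADIUS_M

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.X.eliminate_zeros()
        if self.X.shape != (len(self.tract_ids), len(self.park_ids)):
            raise ValueError("incidence shape does not match id lists")
        if self.X.nnz and (self.X.data < 0).any():
            raise ValueError("incidence entries must be non-negative")

    @property
    def n_tracts(self) -> int:
        return len(self.tract_ids)

    @property
    def n_parks(self) -> int:
        return len(self.park_ids)

    @property
    def total_weight(self) -> int:
        """m: total number of potential park visits."""
        return int(self.X.sum())

    @property
    def n_links(self) -> int:
        """L: number of tract-park pairs with at least one potential visit."""
        return int(self.X.nnz)

    def tract_strengths(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def park_strengths(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()


class ParkProximityIndex:
    """Answers 'which parks lie within r meters of this point'."""

    def __init__(self, parks: Sequence[Park]):
        self.parks = list(parks)
        self._tree = STRtree([p.region for p in self.parks])

    def exposed(self, point: Point, radius_m: float) -> set[str]:
        hits = self._tree.query(point, predicate="dwithin", distance=radius_m)
        return {self.parks[int(i)].park_id for i in hits}

    def exposed_many(self, xs: np.ndarray, ys: np.ndarray, radius_m: float):
        """(point_index, park_index) pairs for all exposures; vectorized."""
        from shapely import points as make_points

        if len(xs) == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        pts = make_points(np.column_stack([xs, ys]))
        return self._tree.query(pts, predicate="dwithin", distance=radius_m)


def exposed_parks(point: Point, parks: Sequence[Park],
                  radius_m: float = DEFAULT_RADIUS_M) -> set[str]:
    """Park ids whose polygon lies within radius_m of the point.

    A point inside a park has distance 0 to it and is therefore exposed.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    return ParkProximityIndex(parks).exposed(point, radius_m)


@dataclass
class BuildReport:
    n_trajectories: int = 0
    n_dropped_no_tract: int = 0
    n_other_activities: int = 0
    n_other_with_exposure: int = 0
    n_trajectories_with_exposure: int = 0


def build_incidence(trajectories: Iterable[Trajectory], tracts: Sequence[Tract],
                    parks: Sequence[Park], radius_m: float = DEFAULT_RADIUS_M,
                    ) -> tuple[ExposureNetwork, BuildReport]:
    """Construct the tract-park incidence matrix.

    X[i, j] counts other-activities whose agent's home lies in tract i and
    whose point lies within radius_m of park j.  One activity exposed to k
    parks contributes 1 to each of the k entries.  Trajectories whose home
    falls in no tract are dropped and counted in the report.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    trajectories = list(trajectories)
    tract_ids = [t.tract_id for t in tracts]
    park_ids = [p.park_id for p in parks]
    tract_pos = {tid: i for i, tid in enumerate(tract_ids)}
    park_pos = {pid: j for j, pid in enumerate(park_ids)}

    report = BuildReport(n_trajectories=len(trajectories))

    tindex = TractIndex(tracts)
    home_x = np.array([t.home.x for t in trajectories], dtype=float)
    home_y = np.array([t.home.y for t in trajectories], dtype=float)
    home_tract = tindex.assign_many(home_x, home_y) if trajectories else []

    # flatten other-activities of kept trajectories
    act_x, act_y, act_row, act_traj = [], [], [], []
    for k, (traj, tid) in enumerate(zip(trajectories, home_tract)):
        if tid is None:
            report.n_dropped_no_tract += 1
            continue
        i = tract_pos[tid]
        for a in traj.others:
            act_x.append(a.x)
            act_y.append(a.y)
            act_row.append(i)
            act_traj.append(k)
    report.n_other_activities = len(act_x)

    pindex = ParkProximityIndex(parks)
    if parks and act_x:
        pt_idx, park_idx = pindex.exposed_many(
            np.asarray(act_x), np.asarray(act_y), radius_m)
    else:
        pt_idx = np.empty(0, dtype=int)
        park_idx = np.empty(0, dtype=int)

    rows = np.asarray([act_row[int(i)] for i in pt_idx], dtype=int)
    cols = np.asarray(park_idx, dtype=int)
    X = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(tract_ids), len(park_ids)),
    ).tocsr()

    exposed_pts = set(int(i) for i in pt_idx)
    report.n_other_with_exposure = len(exposed_pts)
    report.n_trajectories_with_exposure = len({act_traj[i] for i in exposed_pts})
    if report.n_dropped_no_tract:
        logger.info("%d trajectories dropped: home outside every tract",
                    report.n_dropped_no_tract)

    net = ExposureNetwork(X=X, tract_ids=tract_ids, park_ids=park_ids, radius_m=radius_m)
    return net, report


@dataclass(frozen=True)
class NetworkSummary:
    """Node, link and weight totals plus the derived average ratios."""

    n_tracts: int
    n_parks: int
    n_links: int
    total_weight: int

    @classmethod
    def from_network(cls, net: ExposureNetwork) -> "NetworkSummary":
        return cls(net.n_tracts, net.n_parks, net.n_links, net.total_weight)

    def _ratio(self, num: float, den: float) -> float | None:
        return num / den if den else None

    @property
    def mean_weight(self) -> float | None:
        """m / L: average potential visits per link."""
        return self._ratio(self.total_weight, self.n_links)

    @property
    def mean_park_demand(self) -> float | None:
        """m / N_P: average potential visits a park receives."""
        return self._ratio(self.total_weight, self.n_parks)

    @property
    def mean_tract_exposure(self) -> float | None:
        """m / N_T: average park exposure of a tract."""
        return self._ratio(self.total_weight, self.n_tracts)

    @property
    def mean_parks_per_tract(self) -> float | None:
        """L / N_T: average number of distinct parks a tract links to."""
        return self._ratio(self.n_links, self.n_tracts)

    def as_dict(self) -> dict:
        return {
            "N_T": self.n_tracts,
            "N_P": self.n_parks,
            "L": self.n_links,
            "m": self.total_weight,
            "m_over_L": self.mean_weight,
            "m_over_NP": self.mean_park_demand,
            "m_over_NT": self.mean_tract_exposure,
            "L_over_NT": self.mean_parks_per_tract,
        }


def render_integer(value: float | None, mode: str = "nearest",
                   nearest_multiple: int = 1) -> int | None:
    """Paper-style integer rendering of a ratio.

    mode='truncate' drops the fractional part; mode='nearest' rounds half away
    from zero.  nearest_multiple rounds to the closest multiple (e.g. 10).
    """
    if value is None:
        return None
    scaled = value / nearest_multiple
    if mode == "truncate":
        result = int(scaled)
    elif mode == "nearest":
        result = int(np.floor(scaled + 0.5)) if scaled >= 0 else -int(np.floor(-scaled + 0.5))
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return result * nearest_multiple
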