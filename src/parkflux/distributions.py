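"""Distributional summaries: log-binned densities, log-normal fits, mean
visited-park area, and median home-to-other travel distance."""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposureNetwork, Trajectory
from .geo_core import Park, Tract, TractIndex
from .node_metrics import neighbor_weighted_average

M_PER_KM = 1000.0


@dataclass
class LogBinnedDensity:
    bin_edges: np.ndarray  # geometric, length n_bins + 1
    density: np.ndarray    # per-unit density, length n_bins
    counts: np.ndarray
    n_zero_excluded: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1],
            "bin_high": self.bin_edges[1:],
            "count": self.counts,
            "density": self.density,
        })


def log_binned_density(values: Iterable[float], n_bins: int) -> LogBinnedDensity:
    """Histogram on geometrically spaced bins, normalized to a density.

    Non-positive values are excluded and counted.  Bins are left-closed,
    right-open; the final bin is closed on both sides.  The density integrates
    to 1 over the included values.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    v = np.asarray(list(values), dtype=float)
    pos = v[v > 0]
    n_excluded = len(v) - len(pos)
    if len(pos) == 0:
        raise ValueError("no positive values to bin")
    lo, hi = pos.min(), pos.max()
    if lo == hi:
        hi = lo * (1 + 1e-9)
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[0] = lo  # guard float drift at the boundaries
    edges[-1] = hi
    counts, _ = np.histogram(pos, bins=edges)
    widths = np.diff(edges)
    density = counts / (counts.sum() * widths)
    return LogBinnedDensity(edges, density, counts, n_excluded)


@dataclass
class LogNormalFit:
    """ML log-normal fit; mu/sigma on both log and natural scales."""

    mu_log: float
    sigma_log: float
    n: int

    @property
    def mu_natural(self) -> float:
        """Mean of the fitted log-normal on the original scale."""
        return math.exp(self.mu_log + self.sigma_log ** 2 / 2)

    @property
    def sigma_natural(self) -> float:
        """Standard deviation of the fitted log-normal on the original scale."""
        return self.mu_natural * math.sqrt(math.expm1(self.sigma_log ** 2))

    @property
    def median_natural(self) -> float:
        """exp(mu_log) — the alternative 'natural scale' location reading."""
        return math.exp(self.mu_log)

    def as_dict(self) -> dict:
        return {
            "mu_log": self.mu_log,
            "sigma_log": self.sigma_log,
            "mu_natural": self.mu_natural,
            "sigma_natural": self.sigma_natural,
            "median_natural": self.median_natural,
            "n": self.n,
        }


def fit_lognormal(values: Iterable[float]) -> LogNormalFit:
    """Maximum-likelihood log-normal fit: normal ML on the log of the values."""
    v = np.asarray(list(values), dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    if (v <= 0).any():
        raise ValueError("all values must be positive")
    logs = np.log(v)
    sigma = float(logs.std(ddof=0))
    if sigma == 0:
        raise ValueError("degenerate sample: all values identical")
    return LogNormalFit(mu_log=float(logs.mean()), sigma_log=sigma, n=len(v))


def mean_visited_park_area(net: ExposureNetwork, parks: Sequence[Park]) -> pd.Series:
    """Visit-weighted mean area (km^2) of the parks each tract is exposed to."""
    by_id = {p.park_id: p for p in parks}
    areas = np.array([by_id[pid].area_km2 for pid in net.park_ids])
    vals = neighbor_weighted_average(net, areas, side="park")
    return pd.Series(vals, index=net.tract_ids, name="mean_visited_park_area_km2")


def trajectory_median_distance_km(traj: Trajectory) -> float | None:
    """Median euclidean home-to-other distance of one trajectory, in km."""
    if traj.n_other == 0:
        return None
    hx, hy = traj.home.x, traj.home.y
    d = [math.hypot(a.x - hx, a.y - hy) for a in traj.others]
    return float(np.median(d)) / M_PER_KM


def median_home_other_distance(trajectories: Sequence[Trajectory],
                               tracts: Sequence[Tract],
                               ) -> tuple[pd.Series, dict]:
    """Per-tract median of the per-trajectory median travel distances (km).

    Trajectories without other-activities or with homes outside every tract
    are excluded and counted.  The returned report includes the city-level
    mean +- sd over tracts.
    """
    tindex = TractIndex(tracts)
    per_tract: dict[str, list[float]] = {}
    n_no_others = 0
    n_no_tract = 0
    for traj in trajectories:
        med = trajectory_median_distance_km(traj)
        if med is None:
            n_no_others += 1
            continue
        tid = tindex.assign(traj.home.point)
        if tid is None:
            n_no_tract += 1
            continue
        per_tract.setdefault(tid, []).append(med)
    values = pd.Series(
        {tid: float(np.median(v)) for tid, v in sorted(per_tract.items())},
        name="median_travel_km", dtype=float)
    report = {
        "n_trajectories": len(trajectories),
        "n_excluded_no_others": n_no_others,
        "n_excluded_no_tract": n_no_tract,
        "city_mean_km": float(values.mean()) if len(values) else None,
        "city_sd_km": float(values.std(ddof=1)) if len(values) > 1 else None,
    }
    return values, report
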