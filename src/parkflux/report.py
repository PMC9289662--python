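"""End-to-end pipeline orchestration and report assembly."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pfio
from .communities import (Partition, bipartite_modularity, detect_communities,
                          mutual_information, permutation_null_mi)
from .distributions import (fit_lognormal, mean_visited_park_area,
                            median_home_other_distance)
from .exposure import (DEFAULT_RADIUS_M, NetworkSummary, build_incidence,
                       render_integer)
from .geo_core import (merge_overlapping_parks, park_area_fraction,
                       total_park_area_km2, urban_park_area_km2)
from .node_metrics import (GroupLabels, group_crosstabs, homophily,
                           homophily_summary, label_parks, label_tracts,
                           park_group_proportions)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    tracts_path: str
    parks_path: str
    trajectories_path: str
    out_dir: str
    demographics_csv: Optional[str] = None
    radius_m: float = DEFAULT_RADIUS_M
    urban_park_threshold_km2: float = 1.0
    n_permutations: int = 5000
    seed: int = 0
    rounding: str = "nearest"  # "nearest" | "truncate"
    merge_parks: bool = True

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("radius_m must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _check_exists(path: str, what: str) -> None:
    if not Path(path).exists():
        raise FileNotFoundError(f"{what} not found: {path}")


def run_pipeline(config: RunConfig) -> dict:
    """merge -> build -> metrics -> communities -> distributions.

    Writes CSV/JSON artifacts under config.out_dir and returns the summary
    report dict.  Deterministic given identical inputs and seed.
    """
    for p, what in ((config.tracts_path, "tracts file"),
                    (config.parks_path, "parks file"),
                    (config.trajectories_path, "trajectories file")):
        _check_exists(p, what)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tracts = pfio.read_tracts_geojson(config.tracts_path,
                                      demographics_csv=config.demographics_csv)
    parks_raw = pfio.read_parks_geojson(config.parks_path)
    parks = merge_overlapping_parks(parks_raw) if config.merge_parks else parks_raw

    trajectories = pfio.read_trajectories_csv(config.trajectories_path)
    net, build_report = build_incidence(trajectories, tracts, parks,
                                        radius_m=config.radius_m)
    summary = NetworkSummary.from_network(net)

    # --- data / filtering summary (population, areas, exposure counts) ---
    sT = net.tract_strengths()
    sP = net.park_strengths()
    data_summary = {
        "population": int(sum(t.population for t in tracts)),
        "city_area_km2": float(sum(t.area_km2 for t in tracts)),
        "n_tracts_raw": len(tracts),
        "n_tracts_connected": int((sT > 0).sum()),
        "n_parks_input": len(parks_raw),
        "n_parks_merged": len(parks),
        "n_parks_connected": int((sP > 0).sum()),
        "park_area_km2": total_park_area_km2(parks),
        "urban_park_area_km2": urban_park_area_km2(
            parks, config.urban_park_threshold_km2),
        "n_urban_parks": sum(
            1 for p in parks if p.area_km2 < config.urban_park_threshold_km2),
        "n_trajectories": build_report.n_trajectories,
        "n_trajectories_dropped_no_tract": build_report.n_dropped_no_tract,
        "n_other_activities": build_report.n_other_activities,
        "n_other_with_park_exposure": build_report.n_other_with_exposure,
        "n_trajectories_with_park_exposure": build_report.n_trajectories_with_exposure,
    }

    mode = config.rounding
    network_summary = summary.as_dict()
    network_summary.update({
        "m_over_NP_int": render_integer(summary.mean_park_demand, mode),
        "m_over_NT_int": render_integer(summary.mean_tract_exposure, mode),
        "L_over_NT_int": render_integer(summary.mean_parks_per_tract, mode),
    })

    # --- node metrics ---
    t_labels = label_tracts(tracts)
    p_labels = label_parks(net, tracts)
    hT, hP = homophily(net, t_labels, p_labels)
    overview, regional = group_crosstabs(tracts, parks, t_labels, p_labels)
    hT_summary = homophily_summary(hT, t_labels)
    hP_summary = homophily_summary(hP, p_labels)

    pd.DataFrame({
        "tract_id": net.tract_ids,
        "strength": sT,
        "label": t_labels.labels,
        "tie": t_labels.tie_flag,
        "homophily": hT,
    }).to_csv(out / "tract_metrics.csv", index=False)
    pd.DataFrame({
        "park_id": net.park_ids,
        "strength": sP,
        "label": p_labels.labels,
        "tie": p_labels.tie_flag,
        "homophily": hP,
    }).to_csv(out / "park_metrics.csv", index=False)
    overview.to_csv(out / "group_overview.csv")
    regional.to_csv(out / "group_regional.csv")
    hT_summary.to_csv(out / "homophily_tracts.csv")
    hP_summary.to_csv(out / "homophily_parks.csv")

    # --- communities + mutual information ---
    communities_report: dict = {}
    if net.total_weight > 0:
        part = detect_communities(net, seed=config.seed)
        pd.DataFrame({
            "node_id": net.tract_ids + net.park_ids,
            "side": ["tract"] * net.n_tracts + ["park"] * net.n_parks,
            "community": np.concatenate([part.tract_comm, part.park_comm]),
        }).to_csv(out / "communities.csv", index=False)
        communities_report["k"] = part.k
        communities_report["Q"] = part.q

        def _mi_block(group_labels, comm, n, seed):
            labels = [g if g is not None else None for g in group_labels]
            comm_labels = [int(c) if c >= 0 else None for c in comm]
            pairs_ok = any(a is not None and b is not None
                           for a, b in zip(labels, comm_labels))
            if not pairs_ok:
                return None
            res = permutation_null_mi(labels, comm_labels,
                                      n=n, seed=seed)
            return res.as_dict()

        communities_report["mi_tracts"] = _mi_block(
            t_labels.labels, part.tract_comm, config.n_permutations, config.seed)
        communities_report["mi_parks"] = _mi_block(
            p_labels.labels, part.park_comm, config.n_permutations, config.seed + 1)

    # --- distributions ---
    distributions_report: dict = {}
    frac = park_area_fraction(tracts, parks)
    pd.Series(frac, name="park_area_fraction").rename_axis("tract_id").to_csv(
        out / "park_area_fraction.csv")
    mvpa = mean_visited_park_area(net, parks)
    mvpa.rename_axis("tract_id").to_csv(out / "mean_visited_park_area.csv")
    med, med_report = median_home_other_distance(trajectories, tracts)
    med.rename_axis("tract_id").to_csv(out / "median_travel_distance.csv")
    distributions_report["travel_distance"] = med_report
    positive_demand = sP[sP > 0]
    if len(positive_demand) >= 3 and len(np.unique(positive_demand)) > 1:
        distributions_report["park_demand_lognormal"] = fit_lognormal(
            positive_demand).as_dict()

    report = {
        "config": {
            "radius_m": config.radius_m,
            "urban_park_threshold_km2": config.urban_park_threshold_km2,
            "n_permutations": config.n_permutations,
            "seed": config.seed,
            "rounding": config.rounding,
        },
        "data": data_summary,
        "network": network_summary,
        "communities": communities_report,
        "distributions": distributions_report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    pfio.write_network(net, out / "network.mtx")
    return report
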