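"""Node-level network metrics: strengths, weighted neighbor averages,
predominant-group labels, homophily, and group crosstabs."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo_core import GROUP_ORDER, LABELABLE_GROUPS, Park, Tract
from .exposure import ExposureNetwork


@dataclass
class GroupLabels:
    """Predominant-group label per node; NaN-free via None for unlabeled nodes."""

    side: str  # "tract" or "park"
    labels: list[Optional[str]]
    tie_flag: list[bool]

    def as_series(self, index: Sequence[str]) -> pd.Series:
        return pd.Series(self.labels, index=list(index), dtype=object)


def tract_strength(net: ExposureNetwork) -> np.ndarray:
    """s^T: row sums of the incidence — each tract's total park exposure."""
    return net.tract_strengths()


def park_strength(net: ExposureNetwork) -> np.ndarray:
    """s^P: column sums of the incidence — each park's demand."""
    return net.park_strengths()


def neighbor_weighted_average(net: ExposureNetwork, values: np.ndarray,
                              side: str) -> np.ndarray:
    """Visit-weighted mean of an attribute over a node's cross-side neighbors.

    ``side`` names the side the attribute lives on; the result is on the
    opposite side.  Zero-strength nodes get NaN, never a silent zero.
    """
    values = np.asarray(values, dtype=float)
    if side == "park":
        if len(values) != net.n_parks:
            raise ValueError("attribute length must equal number of parks")
        s = net.tract_strengths().astype(float)
        num = net.X @ values
    elif side == "tract":
        if len(values) != net.n_tracts:
            raise ValueError("attribute length must equal number of tracts")
        s = net.park_strengths().astype(float)
        num = net.X.T @ values
    else:
        raise ValueError("side must be 'tract' or 'park'")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, num / np.where(s > 0, s, 1.0), np.nan)
    return out


def _argmax_label(scores: dict[str, float], candidates: Sequence[str]) -> tuple[str, bool]:
    best = max(scores.get(g, 0.0) for g in candidates)
    winners = [g for g in candidates if scores.get(g, 0.0) == best]
    # first in GROUP_ORDER wins ties
    winner = next(g for g in candidates if g in winners)
    return winner, len(winners) > 1


def label_tracts(tracts: Sequence[Tract]) -> GroupLabels:
    """Label each tract by its most populous group; GROUP_ORDER breaks ties.

    The argmax runs over all five categories, but a tract whose predominant
    category is Other is flagged and left unlabeled (the four named groups are
    the only admissible labels).
    """
    labels: list[Optional[str]] = []
    ties: list[bool] = []
    for t in tracts:
        counts = {g: t.group_counts.get(g, 0) for g in GROUP_ORDER}
        winner, tie = _argmax_label(counts, GROUP_ORDER)
        if winner == "Other":
            import warnings

            warnings.warn(f"tract {t.tract_id!r} has Other as predominant group; unlabeled")
            labels.append(None)
        else:
            labels.append(winner)
        ties.append(tie)
    return GroupLabels(side="tract", labels=labels, tie_flag=ties)


def park_group_proportions(net: ExposureNetwork, tracts: Sequence[Tract]) -> pd.DataFrame:
    """Estimated visitor composition of each park: visit-weighted average of the
    home tracts' group fractions.  Rows sum to 1 for connected parks."""
    by_id = {t.tract_id: t for t in tracts}
    cols = {}
    for g in GROUP_ORDER:
        alpha = np.array(
            [by_id[tid].group_fractions()[g] if tid in by_id else 0.0
             for tid in net.tract_ids])
        cols[g] = neighbor_weighted_average(net, alpha, side="tract")
    return pd.DataFrame(cols, index=net.park_ids)


def label_parks(net: ExposureNetwork, tracts: Sequence[Tract]) -> GroupLabels:
    """Label each park by the largest of its estimated visitor proportions over
    the four named groups; zero-strength parks stay unlabeled."""
    props = park_group_proportions(net, tracts)
    s = net.park_strengths()
    labels: list[Optional[str]] = []
    ties: list[bool] = []
    for j, pid in enumerate(net.park_ids):
        if s[j] == 0:
            labels.append(None)
            ties.append(False)
            continue
        row = props.iloc[j].to_dict()
        winner, tie = _argmax_label(row, LABELABLE_GROUPS)
        labels.append(winner)
        ties.append(tie)
    return GroupLabels(side="park", labels=labels, tie_flag=ties)


def homophily(net: ExposureNetwork, tract_labels: GroupLabels,
              park_labels: GroupLabels) -> tuple[np.ndarray, np.ndarray]:
    """Weighted fraction of each node's neighbors sharing its label.

    h^T_i = (1/s^T_i) sum_j X_ij [g^T_i == g^P_j], and symmetrically for
    parks.  Zero-strength or unlabeled nodes get NaN.
    """
    tl = np.array([x if x is not None else "\0" for x in tract_labels.labels], dtype=object)
    pl = np.array([x if x is not None else "\1" for x in park_labels.labels], dtype=object)
    sT = net.tract_strengths().astype(float)
    sP = net.park_strengths().astype(float)
    hT = np.full(net.n_tracts, np.nan)
    hP = np.full(net.n_parks, np.nan)
    Xc = net.X.tocoo()
    sameT = np.zeros(net.n_tracts)
    sameP = np.zeros(net.n_parks)
    for i, j, w in zip(Xc.row, Xc.col, Xc.data):
        if tl[i] == pl[j]:
            sameT[i] += w
            sameP[j] += w
    labeledT = np.array([x is not None for x in tract_labels.labels])
    labeledP = np.array([x is not None for x in park_labels.labels])
    okT = (sT > 0) & labeledT
    okP = (sP > 0) & labeledP
    hT[okT] = sameT[okT] / sT[okT]
    hP[okP] = sameP[okP] / sP[okP]
    return hT, hP


def homophily_summary(h: np.ndarray, labels: GroupLabels) -> pd.DataFrame:
    """Mean +- sd of homophily per group label, NaNs excluded."""
    rows = []
    for g in LABELABLE_GROUPS:
        vals = np.array([v for v, lab in zip(h, labels.labels)
                         if lab == g and np.isfinite(v)])
        rows.append({
            "group": g,
            "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("group")


def assign_parks_to_tracts(parks: Sequence[Park], tracts: Sequence[Tract],
                           rule: str = "centroid") -> list[Optional[str]]:
    """Host tract of each park, for regional crosstabs.

    rule='centroid': tract covering the park centroid (representative point if
    the centroid falls outside the park).  rule='largest-overlap': tract with
    the greatest intersection area.
    """
    from .geo_core import TractIndex

    if rule == "centroid":
        tindex = TractIndex(tracts)
        out = []
        for p in parks:
            c = p.region.centroid
            if not p.region.covers(c):
                c = p.region.representative_point()
            out.append(tindex.assign(c))
        return out
    if rule == "largest-overlap":
        out = []
        for p in parks:
            best_id, best_area = None, 0.0
            for t in tracts:
                a = p.region.intersection(t.region).area
                if a > best_area or (a == best_area and a > 0 and
                                     (best_id is None or t.tract_id < best_id)):
                    best_id, best_area = t.tract_id, a
            out.append(best_id)
        return out
    raise ValueError(f"unknown assignment rule {rule!r}")


def group_crosstabs(tracts: Sequence[Tract], parks: Sequence[Park],
                    tract_labels: GroupLabels, park_labels: GroupLabels,
                    assignment_rule: str = "centroid",
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level composition tables.

    Returns (overview, regional):

    * overview — per group: tract count, % of total city area, park count,
      % of total park area.
    * regional — parks located inside each group's tract region, broken down
      by park label as row-normalized percentages plus a Total count column.
    """
    t_lab = tract_labels.labels
    p_lab = park_labels.labels
    city_area = sum(t.region.area for t in tracts)
    park_area = sum(p.region.area for p in parks)

    overview_rows = []
    for g in LABELABLE_GROUPS:
        g_tracts = [t for t, lab in zip(tracts, t_lab) if lab == g]
        g_parks = [p for p, lab in zip(parks, p_lab) if lab == g]
        overview_rows.append({
            "group": g,
            "tracts": len(g_tracts),
            "pct_city_area": 100.0 * sum(t.region.area for t in g_tracts) / city_area
            if city_area else np.nan,
            "parks": len(g_parks),
            "pct_park_area": 100.0 * sum(p.region.area for p in g_parks) / park_area
            if park_area else np.nan,
        })
    overview = pd.DataFrame(overview_rows).set_index("group")

    host = assign_parks_to_tracts(parks, tracts, rule=assignment_rule)
    tract_label_by_id = {t.tract_id: lab for t, lab in zip(tracts, t_lab)}
    regional_rows = []
    for g in LABELABLE_GROUPS:
        in_region = [p_lab[k] for k, h in enumerate(host)
                     if h is not None and tract_label_by_id.get(h) == g
                     and p_lab[k] is not None]
        total = len(in_region)
        row = {"region": g}
        for pg in LABELABLE_GROUPS:
            row[f"{pg}_pct"] = 100.0 * in_region.count(pg) / total if total else np.nan
        row["total"] = total
        regional_rows.append(row)
    regional = pd.DataFrame(regional_rows).set_index("region")
    return overview, regional
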