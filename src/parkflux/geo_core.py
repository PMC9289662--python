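"""Planar geometry data model: tracts, parks, tag filtering, merging, containment.

All geometric operations in this package assume coordinates are already in a
planar metric system (meters).  The I/O layer is responsible for projecting
geographic coordinates before anything here is called; buffer radii and
euclidean distances are meaningless in degrees.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, MultiPolygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

#: Fixed ordering of demographic groups, used for deterministic tie-breaking.
GROUP_ORDER: tuple[str, ...] = ("White", "Black", "Asian", "Hispanic", "Other")

#: Groups eligible to label a node (``Other`` never wins a label).
LABELABLE_GROUPS: tuple[str, ...] = GROUP_ORDER[:-1]

#: Tag/value pairs that qualify a tagged polygon as a park.
PARK_TAG_VALUES: dict[str, frozenset[str]] = {
    "leisure": frozenset({"park", "dog_park", "playground", "garden", "golf_course"}),
    "landuse": frozenset({"recreation_ground", "nature_reserve"}),
    "natural": frozenset({"beach"}),
    "boundary": frozenset({"protected_area"}),
}

M2_PER_KM2 = 1_000_000.0


def _as_polygonal(geom: BaseGeometry, ident: str) -> BaseGeometry:
    """Return a valid (Multi)Polygon, repairing by make_valid/buffer(0) if needed."""
    if geom is None or geom.is_empty:
        raise ValueError(f"geometry of {ident!r} is empty")
    if not geom.is_valid:
        repaired = make_valid(geom)
        if repaired.geom_type == "GeometryCollection":
            polys = [g for g in repaired.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            repaired = unary_union(polys) if polys else repaired
        if not repaired.is_valid or repaired.is_empty:
            repaired = geom.buffer(0)
        if not repaired.is_valid or repaired.is_empty:
            raise ValueError(f"could not repair invalid geometry of {ident!r}")
        geom = repaired
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"geometry of {ident!r} is {geom.geom_type}, expected polygonal")
    return geom


@dataclass(frozen=True)
class Tract:
    """A census tract: polygon plus per-group population counts."""

    tract_id: str
    region: BaseGeometry
    group_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", _as_polygonal(self.region, self.tract_id))
        if self.region.area <= 0:
            raise ValueError(f"tract {self.tract_id!r} has zero area")
        for g, c in self.group_counts.items():
            if c < 0:
                raise ValueError(f"tract {self.tract_id!r}: negative count for {g!r}")

    @property
    def population(self) -> int:
        return int(sum(self.group_counts.values()))

    @property
    def area_km2(self) -> float:
        return self.region.area / M2_PER_KM2

    def group_fractions(self) -> dict[str, float]:
        """Population share of each group in GROUP_ORDER (zeros if unpopulated)."""
        pop = self.population
        if pop == 0:
            return {g: 0.0 for g in GROUP_ORDER}
        return {g: self.group_counts.get(g, 0) / pop for g in GROUP_ORDER}


@dataclass(frozen=True)
class Park:
    """A park polygon; after merging, park regions are pairwise interior-disjoint."""

    park_id: str
    region: BaseGeometry
    source_tags: tuple[str, ...] = ()
    absorbed_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", _as_polygonal(self.region, self.park_id))

    @property
    def area_km2(self) -> float:
        return self.region.area / M2_PER_KM2


def matches_park_tags(tags: Mapping[str, str]) -> bool:
    """True if the tag map contains any qualifying key/value pair."""
    return any(tags.get(key) in values for key, values in PARK_TAG_VALUES.items())


def filter_osm_parks(records: Iterable[Mapping]) -> tuple[list[Park], int]:
    """Select park polygons from raw tagged records.

    Each record is a mapping with keys ``id``, ``tags`` (str->str) and
    ``geometry`` (shapely polygonal geometry).  Returns the kept parks plus the
    count of records rejected for missing geometry.
    """
    parks: list[Park] = []
    n_rejected = 0
    for rec in records:
        tags = rec.get("tags") or {}
        if not matches_park_tags(tags):
            continue
        geom = rec.get("geometry")
        if geom is None or (hasattr(geom, "is_empty") and geom.is_empty):
            n_rejected += 1
            logger.warning("park record %r has no geometry; rejected", rec.get("id"))
            continue
        tag_strings = tuple(
            f"{k}={v}" for k, v in sorted(tags.items())
            if k in PARK_TAG_VALUES and v in PARK_TAG_VALUES[k]
        )
        parks.append(Park(park_id=str(rec.get("id")), region=geom, source_tags=tag_strings))
    return parks, n_rejected


def _interiors_intersect(a: BaseGeometry, b: BaseGeometry) -> bool:
    # touches == boundary-only contact; such pairs stay separate.
    return a.intersects(b) and not a.touches(b)


def merge_overlapping_parks(parks: Sequence[Park]) -> list[Park]:
    """Dissolve overlapping parks into interior-disjoint polygons.

    Connected components of the pairwise interior-intersection graph are
    geometrically unioned.  Equivalent to iterative pairwise merging but
    deterministic and order-independent.  Each output park lists the input ids
    it absorbed and takes the lexicographically smallest of them as its id.
    """
    n = len(parks)
    if n == 0:
        return []
    geoms = [p.region for p in parks]
    tree = STRtree(geoms)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    left, right = tree.query(geoms, predicate="intersects")
    for i, j in zip(left, right):
        if i < j and _interiors_intersect(geoms[i], geoms[j]):
            union(int(i), int(j))

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    merged: list[Park] = []
    for members in components.values():
        ids = sorted(parks[i].park_id for i in members)
        if len(members) == 1:
            p = parks[members[0]]
            merged.append(Park(p.park_id, p.region, p.source_tags, absorbed_ids=tuple(ids)))
            continue
        region = unary_union([geoms[i] for i in members])
        tags = tuple(sorted({t for i in members for t in parks[i].source_tags}))
        merged.append(Park(ids[0], region, tags, absorbed_ids=tuple(ids)))
    merged.sort(key=lambda p: p.park_id)

    in_area = unary_union(geoms).area
    out_area = sum(p.region.area for p in merged)
    if in_area > 0 and abs(out_area - in_area) > 1e-6 * in_area:
        raise AssertionError(
            f"park merge changed total area: {in_area} -> {out_area}"
        )
    return merged


class TractIndex:
    """Spatial index over interior-disjoint tracts for point assignment."""

    def __init__(self, tracts: Sequence[Tract]):
        self.tracts = list(tracts)
        self._tree = STRtree([t.region for t in self.tracts])

    def assign(self, point: Point) -> str | None:
        # predicate applies input->tree geometry, hence covered_by
        hits = self._tree.query(point, predicate="covered_by")
        if len(hits) == 0:
            return None
        if len(hits) > 1:
            # shared-boundary point: deterministic tie-break by smallest id
            ids = sorted(self.tracts[int(i)].tract_id for i in hits)
            logger.info("point %s on shared boundary of %s; assigned to %s",
                        (point.x, point.y), ids, ids[0])
            return ids[0]
        return self.tracts[int(hits[0])].tract_id

    def assign_many(self, xs: np.ndarray, ys: np.ndarray) -> list[str | None]:
        from shapely import points as make_points

        pts = make_points(np.column_stack([xs, ys]))
        pt_idx, tract_idx = self._tree.query(pts, predicate="covered_by")
        out: list[str | None] = [None] * len(pts)
        for pi, ti in zip(pt_idx, tract_idx):
            tid = self.tracts[int(ti)].tract_id
            prev = out[int(pi)]
            if prev is None or tid < prev:
                out[int(pi)] = tid
        return out


def assign_home_tract(point: Point, tracts: Sequence[Tract]) -> str | None:
    """Tract id containing the point; None if outside all tracts.

    Boundary points are assigned to the tract with the smallest id.
    """
    return TractIndex(tracts).assign(point)


def park_area_fraction(tracts: Sequence[Tract], parks: Sequence[Park]) -> dict[str, float]:
    """Fraction of each tract's area covered by the union of parks, in [0, 1]."""
    for t in tracts:
        if t.region.area <= 0:
            raise ValueError(f"tract {t.tract_id!r} has zero area")
    if not parks:
        return {t.tract_id: 0.0 for t in tracts}
    park_union = unary_union([p.region for p in parks])
    out = {}
    for t in tracts:
        frac = t.region.intersection(park_union).area / t.region.area
        out[t.tract_id] = min(max(frac, 0.0), 1.0)
    return out


def total_park_area_km2(parks: Sequence[Park]) -> float:
    return sum(p.area_km2 for p in parks)


def urban_park_area_km2(parks: Sequence[Park], threshold_km2: float = 1.0) -> float:
    """Total area of parks strictly smaller than the threshold (neighborhood-scale)."""
    return sum(p.area_km2 for p in parks if p.area_km2 < threshold_km2)
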