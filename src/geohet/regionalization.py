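"""Land units, Voronoi regionalization, contiguity and binary spatial weights.

The analysis region is a set of land units (LUs) with planar polygon geometry
in projected meters.  Sparse units can be merged into neighbours, the study
area can be tiled into Thiessen (Voronoi) polygons from unit centroids, and a
queen-style contiguity graph over unit boundaries yields a symmetric binary
spatial-weights matrix W (1 for neighbours, 0 otherwise) together with the
Cliff-Ord weight sums S0, S1, S2 that the Moran variance formulas need.

Near-isolated units within a connection threshold of another unit's border
are attached to their nearest unit by inserting a graph edge (the polygon
geometry is left untouched); units farther than a drop threshold from every
other unit are reported as isolates and excluded from the weights.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon, mapping, shape
from shapely.ops import unary_union

__all__ = [
    "LandUnit",
    "RegionSet",
    "SpatialWeights",
    "aggregate_units",
    "voronoi_partition",
    "build_contiguity",
    "binary_weights",
    "region_from_geojson",
    "region_to_geojson",
    "weights_to_csv",
    "weights_from_csv",
]


@dataclass
class LandUnit:
    """One analytical land unit: polygon in projected meters plus metadata."""

    unit_id: str
    name: str
    polygon: Polygon | MultiPolygon
    centroid: tuple[float, float] | None = None
    sub_centroids: list[tuple[float, float]] | None = None
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError(f"unit {self.unit_id}: invalid or empty polygon")
        if self.centroid is None:
            c = self.polygon.centroid
            self.centroid = (c.x, c.y)


@dataclass
class RegionSet:
    """Land units plus (optional) contiguity structure."""

    units: list[LandUnit]
    adjacency: dict[str, list[str]] = field(default_factory=dict)
    isolates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("unit ids are not unique")
        for i, nbrs in self.adjacency.items():
            for j in nbrs:
                if j == i:
                    raise ValueError(f"self-neighbor at {i}")
                if i not in self.adjacency.get(j, []):
                    raise ValueError(f"asymmetric adjacency: {i}-{j}")

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit(self, unit_id: str) -> LandUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"unknown unit id: {unit_id!r}")


@dataclass
class SpatialWeights:
    """Binary spatial-weights matrix with Cliff-Ord sums.

    S0 = sum_ij w_ij, S1 = 1/2 sum_ij (w_ij + w_ji)^2,
    S2 = sum_i (w_i. + w_.i)^2.
    """

    unit_ids: list[str]
    W: np.ndarray
    S0: float = field(init=False)
    S1: float = field(init=False)
    S2: float = field(init=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape != (len(self.unit_ids),) * 2:
            raise ValueError("W shape does not match unit count")
        if not np.array_equal(W, W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have a zero diagonal")
        if not np.isin(W, (0.0, 1.0)).all():
            raise ValueError("W must be binary")
        self.W = W
        self.S0 = float(W.sum())
        if self.S0 <= 0:
            raise ValueError("W has no nonzero weights")
        self.S1 = float(0.5 * ((W + W.T) ** 2).sum())
        self.S2 = float(((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum())

    @property
    def n(self) -> int:
        return len(self.unit_ids)


# ---------------------------------------------------------------------------
# aggregation

def aggregate_units(region: RegionSet, mapping_: dict[str, str]) -> RegionSet:
    """Merge small units into target units.

    ``mapping_`` maps small-unit id -> target-unit id.  Polygons are unioned,
    sample counts add, sub-centroid lists concatenate (the source centroid is
    kept as a sub-centroid so interpolation can still anchor there), and the
    merged unit keeps the target's id and name.  Chained mappings (a target
    that is itself mapped) are rejected.
    """
    if not mapping_:
        return region
    ids = set(region.unit_ids)
    for src, dst in mapping_.items():
        if src not in ids or dst not in ids:
            raise KeyError(f"unknown unit id in mapping: {src!r} -> {dst!r}")
        if dst in mapping_:
            raise ValueError(f"chained mapping: {src!r} -> {dst!r} -> {mapping_[dst]!r}")
        if src == dst:
            raise ValueError(f"unit mapped to itself: {src!r}")
    merged: list[LandUnit] = []
    for u in region.units:
        if u.unit_id in mapping_:
            continue
        sources = [s for s, d in mapping_.items() if d == u.unit_id]
        if not sources:
            merged.append(u)
            continue
        parts = [u] + [region.unit(s) for s in sources]
        poly = unary_union([p.polygon for p in parts])
        subc = []
        for p in parts:
            subc.extend(p.sub_centroids or [p.centroid])
        merged.append(
            LandUnit(
                unit_id=u.unit_id,
                name=u.name,
                polygon=poly,
                centroid=u.centroid,
                sub_centroids=subc,
                n_samples=sum(p.n_samples for p in parts),
            )
        )
    return RegionSet(units=merged)


def remap_membership(membership: dict, mapping_: dict[str, str]) -> dict:
    """Apply a unit-aggregation mapping to a subject -> unit membership."""
    return {s: mapping_.get(u, u) for s, u in membership.items()}


# ---------------------------------------------------------------------------
# Voronoi tessellation

def _half_plane(ci: np.ndarray, cj: np.ndarray, reach: float) -> Polygon:
    """Rectangle covering the half plane of points nearer ``ci`` than ``cj``."""
    m = (ci + cj) / 2.0
    d = cj - ci
    d = d / np.hypot(*d)
    t = np.array([-d[1], d[0]])
    r = reach
    corners = [m + r * t, m - r * t, m - r * t - 2 * r * d, m + r * t - 2 * r * d]
    return Polygon([tuple(c) for c in corners])


def voronoi_partition(
    centroids: list[tuple[float, float]], bounding_region: Polygon
) -> list[Polygon]:
    """Tile a bounding region into Thiessen polygons, one per centroid.

    Each output polygon ``k`` is the locus of points of the bounding region
    nearer to centroid ``k`` than to any other centroid; built by exact
    half-plane intersection (robust for the tens of units this tool targets).
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("need a non-empty list of (x, y) centroids")
    if len(np.unique(pts, axis=0)) != len(pts):
        raise ValueError("duplicate centroids")
    for p in pts:
        if not bounding_region.covers(Point(*p)):
            raise ValueError(f"centroid {tuple(p)} outside the bounding region")
    if len(pts) == 1:
        return [Polygon(bounding_region.exterior) if isinstance(bounding_region, Polygon) else bounding_region]
    minx, miny, maxx, maxy = bounding_region.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny) + 1.0
    cells = []
    for i, ci in enumerate(pts):
        cell = bounding_region
        for j, cj in enumerate(pts):
            if i == j:
                continue
            cell = cell.intersection(_half_plane(ci, cj, reach))
        cells.append(cell)
    return cells


# ---------------------------------------------------------------------------
# contiguity

def _boundary_distance(a: LandUnit, b: LandUnit) -> float:
    return a.polygon.distance(b.polygon)


def build_contiguity(
    region: RegionSet,
    connect_pairs: list[tuple[str, str]] | None = None,
    connect_threshold: float = 5000.0,
    drop_threshold: float = 10000.0,
    snap_tolerance: float = 1.0,
) -> RegionSet:
    """Detect queen contiguity, repair near-isolates and flag true isolates.

    Units are neighbours when their boundaries share any point (polygon
    distance <= ``snap_tolerance`` meters, absorbing digitization noise).
    A unit left without neighbours is connected to its nearest unit when the
    border-to-border distance is within ``connect_threshold`` (or via the
    explicit ``connect_pairs``); if its nearest unit is farther than
    ``drop_threshold`` it is recorded as an isolate and excluded from the
    spatial weights.
    """
    units = region.units
    adjacency: dict[str, list[str]] = {u.unit_id: [] for u in units}

    def link(i: str, j: str) -> None:
        if j not in adjacency[i]:
            adjacency[i].append(j)
        if i not in adjacency[j]:
            adjacency[j].append(i)

    for a_idx in range(len(units)):
        for b_idx in range(a_idx + 1, len(units)):
            a, b = units[a_idx], units[b_idx]
            if _boundary_distance(a, b) <= snap_tolerance:
                link(a.unit_id, b.unit_id)

    for i, j in connect_pairs or []:
        region.unit(i), region.unit(j)  # existence check
        link(i, j)

    isolates = []
    for u in units:
        if adjacency[u.unit_id]:
            continue
        others = [(v, _boundary_distance(u, v)) for v in units if v.unit_id != u.unit_id]
        if not others:
            isolates.append(u.unit_id)
            continue
        nearest, dist = min(others, key=lambda t: t[1])
        if dist <= connect_threshold:
            link(u.unit_id, nearest.unit_id)
        elif dist > drop_threshold:
            isolates.append(u.unit_id)
            warnings.warn(
                f"unit {u.unit_id} is {dist / 1000.0:.1f} km from its nearest "
                "unit and is excluded as an isolate",
                stacklevel=2,
            )
        else:
            # between thresholds: left unconnected but not dropped
            isolates.append(u.unit_id)
            warnings.warn(
                f"unit {u.unit_id} has no neighbor within "
                f"{connect_threshold / 1000.0:.1f} km; treated as isolate",
                stacklevel=2,
            )
    for iso in isolates:
        adjacency.pop(iso, None)
    return RegionSet(units=list(units), adjacency=adjacency, isolates=isolates)


def binary_weights(region: RegionSet) -> SpatialWeights:
    """Binary spatial weights from the contiguity graph (isolates excluded)."""
    if not region.adjacency:
        raise ValueError("adjacency not built; run build_contiguity first")
    ids = [u.unit_id for u in region.units if u.unit_id not in region.isolates]
    if len(ids) < 2:
        raise ValueError("need at least two non-isolate units")
    index = {u: k for k, u in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    any_edge = False
    for i, nbrs in region.adjacency.items():
        for j in nbrs:
            W[index[i], index[j]] = 1.0
            any_edge = True
    if not any_edge:
        raise ValueError("all units isolated: empty adjacency")
    return SpatialWeights(unit_ids=ids, W=W)


# ---------------------------------------------------------------------------
# I/O

def region_from_geojson(path) -> RegionSet:
    """Read land units from a GeoJSON FeatureCollection.

    Feature properties must carry ``unit_id`` and ``name``; ``n_samples`` and
    ``sub_centroids`` are optional.  Coordinates must already be projected
    (planar meters).
    """
    with open(path) as fh:
        gj = json.load(fh)
    units = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        sub = props.get("sub_centroids")
        units.append(
            LandUnit(
                unit_id=str(props["unit_id"]),
                name=str(props.get("name", props["unit_id"])),
                polygon=shape(feat["geometry"]),
                sub_centroids=[tuple(p) for p in sub] if sub else None,
                n_samples=int(props.get("n_samples", 0)),
            )
        )
    return RegionSet(units=units)


def region_to_geojson(region: RegionSet, path) -> None:
    feats = []
    for u in region.units:
        props = {"unit_id": u.unit_id, "name": u.name, "n_samples": u.n_samples}
        if u.sub_centroids:
            props["sub_centroids"] = [list(p) for p in u.sub_centroids]
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(u.polygon)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def weights_to_csv(weights: SpatialWeights, path) -> None:
    """Dense CSV export: header = unit ids, one labelled row per unit."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", *weights.unit_ids])
        for uid, row in zip(weights.unit_ids, weights.W):
            w.writerow([uid, *(int(v) for v in row)])


def weights_from_csv(path) -> SpatialWeights:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    ids = rows[0][1:]
    W = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return SpatialWeights(unit_ids=ids, W=W)
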