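"""Genetic landscapes: spline interpolation, divergence surfaces, raster I/O.

A *genetic landscape* is a raster surface interpolated from per-land-unit
statistics anchored at unit centroids.  Interpolation uses the regularized
spline with tension — a radial-basis surface that behaves like a thin
flexible plate passing through (or, with smoothing, close to) the data
points:

    z(p) = a1 + sum_j c_j R(r_j),
    R(r) = -[ln(rho) + E1(rho) + gamma],    rho = (phi * r / 2)^2,

with E1 the exponential integral, gamma Euler's constant, phi the tension
(per unit distance) and R(0) = 0 by continuity.  The coefficients solve a
dense linear system with the smoothing parameter added to the diagonal and
the side condition sum_j c_j = 0; at smoothing 0 the surface interpolates
the data exactly.

Model goodness is quantified by the standardized pixelwise divergence
between an observed and a predicted landscape: each cell is
|observed - predicted| / max_rg * 100, where max_rg = max - min of the
observed landscape, so divergences read as percent of the observed range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import exp1
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .regionalization import RegionSet

__all__ = [
    "Surface",
    "PointLayer",
    "DivergenceSummary",
    "build_point_layer",
    "interpolate_rst",
    "divergence_landscape",
    "surface_summary",
    "rank_models",
    "read_ascii_grid",
    "write_ascii_grid",
]

_EULER_GAMMA = float(np.euler_gamma)


@dataclass
class Surface:
    """Regular raster grid in projected meters.

    ``values[0, 0]`` is the north-west cell (rows run north to south, as in
    the ESRI ASCII grid layout); ``origin`` is the lower-left corner
    (xllcorner, yllcorner).  Missing cells carry NaN.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-center coordinates (same shape as ``values``)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.nrows)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def congruent_with(self, other: "Surface") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def clip(self, mask: Polygon) -> "Surface":
        """Set cells whose centers fall outside ``mask`` to NaN."""
        gx, gy = self.cell_centers()
        prepared = prep(mask)
        keep = np.array(
            [prepared.covers(Point(x, y)) for x, y in zip(gx.ravel(), gy.ravel())]
        ).reshape(self.values.shape)
        vals = np.where(keep, self.values, np.nan)
        return Surface(self.origin, self.cell_size, vals, self.nodata)


@dataclass
class PointLayer:
    """Centroid-anchored data points feeding the interpolation."""

    points: list[tuple[tuple[float, float], float]]
    provenance: list[str] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([p for p, _ in self.points], dtype=float)

    def data(self) -> np.ndarray:
        return np.array([v for _, v in self.points], dtype=float)


@dataclass(frozen=True)
class DivergenceSummary:
    """Summary statistics of one model's divergence surface (percent of range)."""

    model_id: str
    mean: float
    sd: float
    median: float
    min: float
    max: float


def build_point_layer(
    region: RegionSet,
    values: dict,
    replicate_sub_centroids: bool = True,
) -> PointLayer:
    """One data point per unit centroid, valued with the unit's statistic.

    Units carrying sub-centroids (e.g. a city pooled over several postal
    areas) emit one point per sub-centroid, all with the unit's single value,
    which smooths the interpolation over their extent.  Units without a value
    are skipped with a warning.
    """
    points, provenance = [], []
    for unit in region.units:
        if unit.unit_id not in values or values[unit.unit_id] is None or (
            isinstance(values[unit.unit_id], float) and np.isnan(values[unit.unit_id])
        ):
            warnings.warn(f"no value for unit {unit.unit_id}; point omitted", stacklevel=2)
            continue
        v = float(values[unit.unit_id])
        anchors = (
            unit.sub_centroids
            if replicate_sub_centroids and unit.sub_centroids
            else [unit.centroid]
        )
        for xy in anchors:
            points.append(((float(xy[0]), float(xy[1])), v))
            provenance.append(unit.unit_id)
    return PointLayer(points=points, provenance=provenance)


def _rst_basis(r: np.ndarray, phi: float) -> np.ndarray:
    """Radial basis R(r) of the regularized spline with tension; R(0) = 0."""
    rho = (phi * np.asarray(r, dtype=float) / 2.0) ** 2
    out = np.zeros_like(rho)
    pos = rho > 0
    out[pos] = -(np.log(rho[pos]) + exp1(rho[pos]) + _EULER_GAMMA)
    return out


def grid_spec(
    bounds: tuple[float, float, float, float], ncols: int = 200
) -> tuple[tuple[float, float], float, int, int]:
    """Square-cell grid spec (origin, cell_size, nrows, ncols) covering bounds."""
    minx, miny, maxx, maxy = bounds
    cell = (maxx - minx) / ncols
    nrows = max(1, int(np.ceil((maxy - miny) / cell)))
    return (minx, miny), cell, nrows, ncols


def interpolate_rst(
    layer: PointLayer,
    origin: tuple[float, float],
    cell_size: float,
    nrows: int,
    ncols: int,
    tension: float = 40.0,
    smoothing: float = 0.1,
    mask: Polygon | None = None,
) -> Surface:
    """Interpolate a point layer to a raster with the tension spline.

    ``tension`` is expressed per map extent (the point bounding box's larger
    side), so its useful range does not depend on the projection units;
    ``smoothing`` relaxes exact interpolation (0 = pass through the data).
    Coincident points with different values require smoothing > 0.
    """
    xy = layer.coords()
    z = layer.data()
    if len(xy) < 3:
        raise ValueError("need at least 3 data points")
    if tension <= 0:
        raise ValueError("tension must be positive")
    if smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    # normalize tension by map extent so the default is scale-free
    ext = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]))
    phi = tension / ext if ext > 0 else tension

    d = np.hypot(xy[:, 0, None] - xy[None, :, 0], xy[:, 1, None] - xy[None, :, 1])
    dup = (d < 1e-9) & ~np.eye(len(xy), dtype=bool)
    if smoothing == 0 and dup.any():
        i, j = np.argwhere(dup)[0]
        if not np.isclose(z[i], z[j]):
            raise ValueError(
                "coincident points with different values need smoothing > 0"
            )
    m = len(xy)
    K = _rst_basis(d, phi) + smoothing * np.eye(m)
    # bordered system: [K 1; 1' 0] [c; a1] = [z; 0]
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = K
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    rhs = np.append(z, 0.0)
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular interpolation system: {err}") from err
    c, a1 = sol[:m], sol[m]

    surf = Surface(origin=origin, cell_size=cell_size, values=np.zeros((nrows, ncols)))
    gx, gy = surf.cell_centers()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    r = np.hypot(pts[:, 0, None] - xy[None, :, 0], pts[:, 1, None] - xy[None, :, 1])
    surf.values = (_rst_basis(r, phi) @ c + a1).reshape(nrows, ncols)
    if mask is not None:
        surf = surf.clip(mask)
    return surf


def evaluate_rst_at(
    layer: PointLayer, probes: np.ndarray, tension: float = 40.0, smoothing: float = 0.0
) -> np.ndarray:
    """Evaluate the tension-spline surface at arbitrary probe points."""
    probes = np.asarray(probes, dtype=float)
    n = len(probes)
    # reuse the raster path with one cell per probe: solve once, evaluate there
    xy = layer.coords()
    z = layer.data()
    ext = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]))
    phi = tension / ext if ext > 0 else tension
    d = np.hypot(xy[:, 0, None] - xy[None, :, 0], xy[:, 1, None] - xy[None, :, 1])
    m = len(xy)
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = _rst_basis(d, phi) + smoothing * np.eye(m)
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    sol = np.linalg.solve(A, np.append(z, 0.0))
    c, a1 = sol[:m], sol[m]
    r = np.hypot(probes[:, 0, None] - xy[None, :, 0], probes[:, 1, None] - xy[None, :, 1])
    return _rst_basis(r, phi) @ c + a1


def divergence_landscape(
    observed: Surface, predicted: Surface
) -> tuple[Surface, float]:
    """Standardized pixelwise divergence between two congruent landscapes.

    Each cell is |observed - predicted| / max_rg * 100 with
    max_rg = max(observed) - min(observed) over valid cells; NaN propagates.
    Returns the divergence surface and max_rg.
    """
    if not observed.congruent_with(predicted):
        raise ValueError("surfaces are not congruent (origin/cell size/shape)")
    valid = ~np.isnan(observed.values)
    if not valid.any():
        raise ValueError("observed surface has no valid cells")
    zmax = float(np.nanmax(observed.values))
    zmin = float(np.nanmin(observed.values))
    max_rg = zmax - zmin
    if max_rg == 0:
        raise ValueError("observed surface is constant: zero range")
    div = np.abs(observed.values - predicted.values) / max_rg * 100.0
    return Surface(observed.origin, observed.cell_size, div, observed.nodata), max_rg


def surface_summary(s: Surface) -> dict[str, float]:
    """Mean, sd (n-1), median, min, max over the valid (non-NaN) cells."""
    vals = s.values[~np.isnan(s.values)]
    if vals.size == 0:
        raise ValueError("surface has no valid cells")
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "median": float(np.median(vals)),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


def rank_models(summaries: list[DivergenceSummary]) -> tuple[str, list[DivergenceSummary]]:
    """Rank models by ascending mean divergence (sd breaks ties).

    Returns the winning model id and the full ranking.
    """
    if not summaries:
        raise ValueError("no summaries to rank")
    ranking = sorted(summaries, key=lambda s: (s.mean, s.sd))
    return ranking[0].model_id, ranking


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)

def write_ascii_grid(s: Surface, path) -> None:
    """Write an ESRI ASCII grid (.asc); NaN cells become the nodata value."""
    vals = np.where(np.isnan(s.values), s.nodata, s.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {s.ncols}\n")
        fh.write(f"nrows {s.nrows}\n")
        fh.write(f"xllcorner {s.origin[0]:.6f}\n")
        fh.write(f"yllcorner {s.origin[1]:.6f}\n")
        fh.write(f"cellsize {s.cell_size:.6f}\n")
        fh.write(f"NODATA_value {s.nodata}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path) -> Surface:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.array(rows)
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match the declared nrows/ncols")
    return Surface(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=vals,
        nodata=nodata,
    )


def surface_to_csv(s: Surface, path) -> None:
    """Export a surface as CSV rows of (x, y, value) for valid cells."""
    gx, gy = s.cell_centers()
    with open(path, "w") as fh:
        fh.write("x,y,value\n")
        for x, y, v in zip(gx.ravel(), gy.ravel(), s.values.ravel()):
            if not np.isnan(v):
                fh.write(f"{x:.3f},{y:.3f},{v:.6f}\n")
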