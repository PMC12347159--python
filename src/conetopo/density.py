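"""Continuous cone-density mapping from annotated cone coordinates.

Density at a query point is estimated from the 150 nearest cone centers:
their Voronoi cell areas (from one global tessellation of all cones) are
summed and density is 150 divided by that total area, i.e. the reciprocal
of the mean exclusive territory of the neighbourhood.  Cells of convex
hull cones are unbounded; any query whose neighbourhood includes one is
marked invalid rather than biased by a clipped cell.

From the resulting map, the peak cone density (PCD) is the single highest
value, and the cone density centroid (CDC) is the density-weighted
centroid of the connected region enclosing the top 20% of density values.
Density at the CDC is the D0 of all downstream profile analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, Voronoi, cKDTree, QhullError

from .mosaic import ConeMosaic

__all__ = [
    "DensityMap",
    "TopographyMetrics",
    "VoronoiDensityEstimator",
    "voronoi_cell_areas",
    "density_at_point",
    "compute_density_map",
    "compute_cdc",
    "iso_density_contour_metrics",
    "cones_in_region",
]

DEFAULT_K = 150


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_cell_areas(mosaic: ConeMosaic | np.ndarray):
    """Per-cone Voronoi cell areas (µm²) from one global tessellation.

    Returns ``(areas, unbounded)``: cones whose cells are not fully
    determined by neighbours get ``unbounded=True`` and a NaN area
    instead of a truncated value.  This covers cells that touch the hull
    at infinity and cells with a vertex outside the convex hull of the
    cones — nearly-collinear border cones produce formally bounded but
    arbitrarily large cells, which are just as unusable for density.
    """
    coords = mosaic.coordinates if isinstance(mosaic, ConeMosaic) else np.asarray(mosaic, float)
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 cones for a Voronoi tessellation")
    try:
        vor = Voronoi(coords)
        hull = Delaunay(coords)
    except QhullError as exc:
        raise ValueError(f"degenerate cone configuration: {exc}") from exc
    vertex_outside = hull.find_simplex(vor.vertices) < 0
    n = coords.shape[0]
    areas = np.full(n, np.nan)
    unbounded = np.zeros(n, dtype=bool)
    for i, region_index in enumerate(vor.point_region):
        region = vor.regions[region_index]
        if len(region) == 0 or -1 in region or vertex_outside[region].any():
            unbounded[i] = True
        else:
            areas[i] = _polygon_area(vor.vertices[region])
    return areas, unbounded


class VoronoiDensityEstimator:
    """k-nearest-cone Voronoi density estimator bound to one mosaic.

    Precomputes the global tessellation and a k-d tree once; queries are
    then vectorised.  Distance ties at identical radius are broken by the
    tree's deterministic internal order; this matters only on perfect
    lattices, where tied cells have identical areas and the estimate is
    unaffected.
    """

    def __init__(self, mosaic: ConeMosaic, k: int = DEFAULT_K):
        if k < 3:
            raise ValueError("k must be >= 3")
        if len(mosaic) < k:
            raise ValueError(f"mosaic has {len(mosaic)} cones, fewer than k={k}")
        self.mosaic = mosaic
        self.k = k
        self.areas, self.unbounded = voronoi_cell_areas(mosaic)
        self.tree = cKDTree(mosaic.coordinates)

    def density(self, points) -> np.ndarray:
        """Density (cones/mm²) at query points; NaN where undefined."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(pts.shape[0])
        chunk = 200_000 // self.k + 1
        for start in range(0, pts.shape[0], chunk):
            sl = slice(start, min(start + chunk, pts.shape[0]))
            _, idx = self.tree.query(pts[sl], k=self.k)
            idx = np.atleast_2d(idx)
            invalid = self.unbounded[idx].any(axis=1)
            total = self.areas[idx].sum(axis=1)
            dens = self.k / total * 1e6  # µm⁻² → mm⁻²
            dens[invalid] = np.nan
            out[sl] = dens
        return out


def density_at_point(
    point, mosaic: ConeMosaic, k: int = DEFAULT_K,
    estimator: Optional[VoronoiDensityEstimator] = None,
) -> float:
    """Cone density (cones/mm²) at one point; NaN outside the reliable region."""
    est = estimator if estimator is not None else VoronoiDensityEstimator(mosaic, k=k)
    return float(est.density(np.asarray(point, float)[None, :])[0])


@dataclass
class DensityMap:
    """Regular grid of cone density values (cones/mm²).

    ``values[i, j]`` is the density at ``(x0 + j·spacing, y0 + i·spacing)``;
    NaN marks grid points where the estimate is undefined (neighbourhood
    touches the hull).
    """

    values: np.ndarray
    grid_origin: Tuple[float, float]
    grid_spacing: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if np.any(self.values[np.isfinite(self.values)] <= 0):
            raise ValueError("valid densities must be > 0")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def x(self) -> np.ndarray:
        return self.grid_origin[0] + self.grid_spacing * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.grid_origin[1] + self.grid_spacing * np.arange(self.values.shape[0])

    def interpolate(self, points) -> np.ndarray:
        """Bilinear interpolation; NaN outside the grid or near invalid cells."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        gx = (pts[:, 0] - self.grid_origin[0]) / self.grid_spacing
        gy = (pts[:, 1] - self.grid_origin[1]) / self.grid_spacing
        ny, nx = self.values.shape
        out = np.full(pts.shape[0], np.nan)
        ok = (gx >= 0) & (gx <= nx - 1) & (gy >= 0) & (gy <= ny - 1)
        if not np.any(ok):
            return out
        j0 = np.clip(np.floor(gx[ok]).astype(int), 0, nx - 2)
        i0 = np.clip(np.floor(gy[ok]).astype(int), 0, ny - 2)
        fx = gx[ok] - j0
        fy = gy[ok] - i0
        v00 = self.values[i0, j0]
        v01 = self.values[i0, j0 + 1]
        v10 = self.values[i0 + 1, j0]
        v11 = self.values[i0 + 1, j0 + 1]
        out[ok] = (
            v00 * (1 - fx) * (1 - fy)
            + v01 * fx * (1 - fy)
            + v10 * (1 - fx) * fy
            + v11 * fx * fy
        )
        return out


@dataclass
class TopographyMetrics:
    """Map-level topography read-outs: PCD, CDC, D0 and top-20% area."""

    pcd: float
    pcd_location: Tuple[float, float]
    cdc_location: Tuple[float, float]
    d0: float
    isoa_top20: float
    truncated: bool = False  # top-20% region touches the valid border

    def as_dict(self) -> dict:
        return {
            "pcd_cones_per_mm2": self.pcd,
            "pcd_location_um": list(self.pcd_location),
            "cdc_location_um": list(self.cdc_location),
            "d0_cones_per_mm2": self.d0,
            "isoa_top20_um2": self.isoa_top20,
            "truncated": bool(self.truncated),
        }


def compute_density_map(
    mosaic: ConeMosaic,
    grid_spacing: float = 1.0,
    extent: Optional[float] = None,
    center: Tuple[float, float] = (0.0, 0.0),
    k: int = DEFAULT_K,
) -> DensityMap:
    """Evaluate the k-nearest-cone density estimator on a regular grid.

    The grid is the square of half-width ``extent`` around ``center``
    (default: 80% of the mosaic's maximum radius, inside which 150-cone
    neighbourhoods rarely touch the hull).
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be > 0")
    if extent is None:
        radius = np.hypot(*(mosaic.coordinates - np.asarray(center)).T).max()
        extent = 0.8 * radius
    est = VoronoiDensityEstimator(mosaic, k=k)
    xs = center[0] + np.arange(-extent, extent + grid_spacing / 2, grid_spacing)
    ys = center[1] + np.arange(-extent, extent + grid_spacing / 2, grid_spacing)
    xx, yy = np.meshgrid(xs, ys)
    values = est.density(np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return DensityMap(values=values, grid_origin=(float(xs[0]), float(ys[0])),
                      grid_spacing=float(grid_spacing))


def _top_region(dmap: DensityMap, level: float, seed_cell: Tuple[int, int]) -> np.ndarray:
    """8-connected super-level component of the map containing seed_cell."""
    mask = dmap.valid_mask & (np.nan_to_num(dmap.values, nan=-np.inf) >= level)
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    lab = labels[seed_cell]
    if lab == 0:
        raise ValueError("seed cell not inside the super-level region")
    return labels == lab


def compute_cdc(dmap: DensityMap) -> TopographyMetrics:
    """Locate PCD and CDC on a density map.

    The CDC is the density-weighted centroid of the 8-connected region of
    grid points with density ≥ 80% of PCD that contains the peak; D0 is
    the bilinearly interpolated map value at the CDC.
    """
    if not np.any(dmap.valid_mask):
        raise ValueError("density map has no valid points")
    flat = np.nan_to_num(dmap.values, nan=-np.inf)
    peak_cell = np.unravel_index(np.argmax(flat), dmap.values.shape)
    pcd = float(dmap.values[peak_cell])
    region = _top_region(dmap, 0.8 * pcd, peak_cell)

    ii, jj = np.nonzero(region)
    w = dmap.values[ii, jj]
    cx = float(np.sum(w * (dmap.grid_origin[0] + jj * dmap.grid_spacing)) / np.sum(w))
    cy = float(np.sum(w * (dmap.grid_origin[1] + ii * dmap.grid_spacing)) / np.sum(w))
    d0 = float(dmap.interpolate([(cx, cy)])[0])

    # truncation warning: region touching array edge or invalid neighbours
    ny, nx = dmap.values.shape
    touches_edge = bool(
        region[0, :].any() or region[-1, :].any()
        or region[:, 0].any() or region[:, -1].any()
    )
    dilated = ndimage.binary_dilation(region, structure=np.ones((3, 3), bool))
    touches_invalid = bool(np.any(dilated & ~dmap.valid_mask))

    pcd_loc = (
        float(dmap.grid_origin[0] + peak_cell[1] * dmap.grid_spacing),
        float(dmap.grid_origin[1] + peak_cell[0] * dmap.grid_spacing),
    )
    return TopographyMetrics(
        pcd=pcd,
        pcd_location=pcd_loc,
        cdc_location=(cx, cy),
        d0=d0,
        isoa_top20=float(region.sum()) * dmap.grid_spacing**2,
        truncated=touches_edge or touches_invalid,
    )


def _extent_through(dmap: DensityMap, cdc, level: float, direction: np.ndarray) -> float:
    """Length of the contiguous super-level interval through the CDC."""
    step = dmap.grid_spacing / 4
    length = 0.0
    for sign in (1.0, -1.0):
        t = 0.0
        while True:
            t += step
            p = np.asarray(cdc, float) + sign * t * direction
            v = dmap.interpolate([p])[0]
            if not np.isfinite(v) or v < level:
                break
        length += t - step
    return length


def iso_density_contour_metrics(dmap: DensityMap, level: float, cdc) -> Tuple[float, float]:
    """Area (µm²) and horizontal/vertical aspect ratio of an iso-density region.

    The region is the connected super-level set containing the CDC; the
    aspect ratio divides its horizontal extent through the CDC by its
    vertical extent.
    """
    valid = dmap.values[dmap.valid_mask]
    if not (valid.min() < level < valid.max()):
        raise ValueError("level must lie strictly inside the map's density range")
    cdc = np.asarray(cdc, dtype=float)
    j = int(round((cdc[0] - dmap.grid_origin[0]) / dmap.grid_spacing))
    i = int(round((cdc[1] - dmap.grid_origin[1]) / dmap.grid_spacing))
    region = _top_region(dmap, level, (i, j))
    area = float(region.sum()) * dmap.grid_spacing**2
    h = _extent_through(dmap, cdc, level, np.array([1.0, 0.0]))
    v = _extent_through(dmap, cdc, level, np.array([0.0, 1.0]))
    if v == 0:
        raise ValueError("degenerate vertical extent")
    return area, h / v


def cones_in_region(
    mosaic: ConeMosaic, center, r_inner: float, r_outer: float
) -> int:
    """Number of cones with r_inner ≤ distance(center) < r_outer."""
    if not (0 <= r_inner < r_outer):
        raise ValueError("require 0 <= r_inner < r_outer")
    r = np.hypot(*(mosaic.coordinates - np.asarray(center, float)).T)
    return int(np.count_nonzero((r >= r_inner) & (r < r_outer)))
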