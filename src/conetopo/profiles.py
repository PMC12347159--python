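"""Profile extraction around the cone density centroid.

Meridional profiles average map values inside narrow isosceles triangle
sectors (5° vertex angle at the CDC); radial profiles average all map
values on circles around the CDC; circular profiles sample one such
circle as a function of angle.  Angles follow the retinal convention
0° = nasal, 90° = superior, with laterality-aware mapping from image
coordinates so left and right eyes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple, Union

import numpy as np

from .density import DensityMap, voronoi_cell_areas
from .mosaic import ConeMosaic
from .sigmoid import SigmoidDecayModel, SigmoidFitResults, SigmoidParams

__all__ = [
    "DensityProfile",
    "CircularProfile",
    "meridional_profile",
    "radial_profile",
    "circular_profile",
    "normalize_profile",
    "intercone_distance_profile",
    "convert_units",
    "profile_slope_metrics",
    "retinal_to_image_angle",
]

_QUADRANT_ANGLES = {"nasal": 0.0, "superior": 90.0, "temporal": 180.0, "inferior": 270.0}
_MERIDIANS = {"horizontal": ("nasal", "temporal"), "vertical": ("superior", "inferior")}


@dataclass
class DensityProfile:
    """Eccentricity → density series (meridional, radial or ICD).

    ``density`` is cones/mm² unless ``units`` says otherwise (the
    intercone-distance profile stores µm).  ``normalized`` profiles hold
    density divided by ``d0_ref``.
    """

    kind: str
    eccentricity: np.ndarray
    density: np.ndarray
    bin_width: float
    normalized: bool = False
    d0_ref: Optional[float] = None
    units: str = "cones_per_mm2"

    def __post_init__(self):
        self.eccentricity = np.asarray(self.eccentricity, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.eccentricity.shape != self.density.shape:
            raise ValueError("eccentricity and density must align")
        if np.any(np.diff(self.eccentricity) <= 0):
            raise ValueError("eccentricity must be strictly increasing")


@dataclass
class CircularProfile:
    """Density versus angle on one circle around the CDC.

    ``theta`` is in retinal degrees (0 = nasal, 90 = superior), strictly
    increasing over [0, 360); the profile is periodic.
    """

    eccentricity: float
    theta: np.ndarray
    density: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.theta.shape != self.density.shape:
            raise ValueError("theta and density must align")
        if np.any(np.diff(self.theta) <= 0) or self.theta[0] < 0 or self.theta[-1] >= 360:
            raise ValueError("theta must be strictly increasing within [0, 360)")


def retinal_to_image_angle(theta_deg, laterality: str):
    """Map retinal angles (0 = nasal, 90 = superior) to image-plane angles.

    OS and synthetic mosaics have nasal at +x; OD mosaics are mirrored
    about the vertical axis.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if laterality == "OD":
        return 180.0 - theta
    return theta


def _sector_profile(
    dmap: DensityMap, cdc, direction_deg: float, vertex_angle: float, bin_width: float
):
    """Mean valid density per eccentricity bin inside one triangle sector."""
    xx, yy = np.meshgrid(dmap.x, dmap.y)
    dx = xx - cdc[0]
    dy = yy - cdc[1]
    ecc = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx))
    diff = np.abs((ang - direction_deg + 180.0) % 360.0 - 180.0)
    in_sector = (diff <= vertex_angle / 2) | (ecc == 0)
    ok = in_sector & dmap.valid_mask
    bins = np.round(ecc[ok] / bin_width).astype(int)
    values = dmap.values[ok]
    count = np.bincount(bins)
    total = np.bincount(bins, weights=values)
    present = count > 0
    return np.nonzero(present)[0] * bin_width, total[present] / count[present]


def meridional_profile(
    dmap: DensityMap,
    cdc,
    direction: Union[str, float],
    vertex_angle: float = 5.0,
    bin_width: Optional[float] = None,
    laterality: str = "synthetic",
) -> DensityProfile:
    """Sector-averaged density profile along a meridian or quadrant.

    ``direction`` is either a retinal angle in degrees, a quadrant name
    (``nasal``/``temporal``/``superior``/``inferior``) or a full meridian
    (``horizontal``/``vertical``), the latter averaging its two opposite
    quadrant sectors per eccentricity.
    """
    if not _cdc_inside(dmap, cdc):
        raise ValueError("CDC lies outside the density map")
    bw = float(bin_width if bin_width is not None else dmap.grid_spacing)
    if isinstance(direction, str) and direction in _MERIDIANS:
        q1, q2 = _MERIDIANS[direction]
        e1, v1 = _sector_profile(
            dmap, cdc, float(retinal_to_image_angle(_QUADRANT_ANGLES[q1], laterality)),
            vertex_angle, bw)
        e2, v2 = _sector_profile(
            dmap, cdc, float(retinal_to_image_angle(_QUADRANT_ANGLES[q2], laterality)),
            vertex_angle, bw)
        ecc = np.intersect1d(e1, e2)
        vals = (
            v1[np.searchsorted(e1, ecc)] + v2[np.searchsorted(e2, ecc)]
        ) / 2.0
        kind = direction
    else:
        if isinstance(direction, str):
            if direction not in _QUADRANT_ANGLES:
                raise ValueError(f"unknown direction {direction!r}")
            angle = _QUADRANT_ANGLES[direction]
            kind = direction
        else:
            angle = float(direction)
            kind = f"sector_{angle:g}deg"
        ecc, vals = _sector_profile(
            dmap, cdc, float(retinal_to_image_angle(angle, laterality)),
            vertex_angle, bw)
    if ecc.size == 0:
        raise ValueError("no valid map values inside the sector")
    return DensityProfile(kind=kind, eccentricity=ecc, density=vals, bin_width=bw)


def _cdc_inside(dmap: DensityMap, cdc) -> bool:
    v = dmap.interpolate([tuple(cdc)])[0]
    return bool(np.isfinite(v))


def _circle_samples(dmap: DensityMap, cdc, ecc: float, angular_step: float,
                    laterality: str):
    theta = np.arange(0.0, 360.0, angular_step)
    img = np.radians(retinal_to_image_angle(theta, laterality))
    pts = np.column_stack(
        [cdc[0] + ecc * np.cos(img), cdc[1] + ecc * np.sin(img)]
    )
    return theta, dmap.interpolate(pts)


def radial_profile(
    dmap: DensityMap,
    cdc,
    step: Optional[float] = None,
    max_ecc: Optional[float] = None,
    angular_step: float = 1.0,
) -> DensityProfile:
    """Radially averaged density profile around the CDC.

    Each value is the mean of bilinear map samples on the circle of that
    eccentricity (1° angular steps); the value at E = 0 is the map value
    at the CDC.  The profile stops at the first circle that leaves the
    valid region.
    """
    if not _cdc_inside(dmap, cdc):
        raise ValueError("CDC lies outside the density map")
    step = float(step if step is not None else dmap.grid_spacing)
    if max_ecc is None:
        span = max(np.ptp(dmap.x), np.ptp(dmap.y))
        max_ecc = span / 2
    eccs = [0.0]
    values = [float(dmap.interpolate([tuple(cdc)])[0])]
    r = step
    while r <= max_ecc + 1e-9:
        _, samples = _circle_samples(dmap, cdc, r, angular_step, "synthetic")
        if not np.isfinite(samples).all():
            break
        eccs.append(r)
        values.append(float(samples.mean()))
        r += step
    return DensityProfile(
        kind="radial", eccentricity=np.array(eccs), density=np.array(values),
        bin_width=step,
    )


def circular_profile(
    dmap: DensityMap,
    cdc,
    eccentricity: float,
    angular_step: float = 1.0,
    laterality: str = "synthetic",
) -> CircularProfile:
    """Density versus retinal angle on one circle around the CDC.

    Rejects circles that exit the valid region (no partial profiles).
    """
    if eccentricity <= 0:
        raise ValueError("eccentricity must be > 0")
    theta, samples = _circle_samples(dmap, cdc, eccentricity, angular_step, laterality)
    if not np.isfinite(samples).all():
        raise ValueError(
            f"circle at {eccentricity} µm exits the valid region"
        )
    return CircularProfile(eccentricity=float(eccentricity), theta=theta, density=samples)


def normalize_profile(profile: DensityProfile, d0: float) -> DensityProfile:
    """Scale a density profile by D0; rejects double normalization."""
    if profile.normalized:
        raise ValueError("profile is already normalized")
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    return replace(
        profile, density=profile.density / d0, normalized=True, d0_ref=float(d0)
    )


def intercone_distance_profile(
    mosaic: ConeMosaic,
    cdc,
    bin_width: float = 2.0,
    smooth_window: float = 11.0,
) -> DensityProfile:
    """Average intercone distance (µm) versus eccentricity from the CDC.

    Per-cone ICD is the mean distance to its Voronoi neighbours; hull
    cones (undefined neighbourhoods) are excluded.  The binned profile is
    smoothed by a centred moving mean of 11 µm, truncated at the ends.
    """
    if len(mosaic) < 150:
        raise ValueError("need at least 150 cones for an ICD profile")
    from scipy.spatial import Voronoi

    coords = mosaic.coordinates
    _, unbounded = voronoi_cell_areas(mosaic)
    vor = Voronoi(coords)
    n = coords.shape[0]
    dist_sum = np.zeros(n)
    dist_cnt = np.zeros(n, dtype=int)
    pair_dist = np.hypot(
        *(coords[vor.ridge_points[:, 0]] - coords[vor.ridge_points[:, 1]]).T
    )
    np.add.at(dist_sum, vor.ridge_points[:, 0], pair_dist)
    np.add.at(dist_sum, vor.ridge_points[:, 1], pair_dist)
    np.add.at(dist_cnt, vor.ridge_points[:, 0], 1)
    np.add.at(dist_cnt, vor.ridge_points[:, 1], 1)
    keep = (~unbounded) & (dist_cnt > 0)
    icd = dist_sum[keep] / dist_cnt[keep]
    ecc = np.hypot(*(coords[keep] - np.asarray(cdc, float)).T)

    bins = np.round(ecc / bin_width).astype(int)
    count = np.bincount(bins)
    total = np.bincount(bins, weights=icd)
    present = count > 0
    centers = np.nonzero(present)[0] * bin_width
    values = total[present] / count[present]

    half = smooth_window / 2.0
    smoothed = np.array([
        values[(centers >= c - half) & (centers <= c + half)].mean() for c in centers
    ])
    return DensityProfile(
        kind="icd", eccentricity=centers, density=smoothed, bin_width=bin_width,
        units="um",
    )


_LENGTHS = {"um", "deg"}
_DENSITIES = {"cones_per_mm2", "cones_per_deg2"}


def convert_units(value, from_unit: str, to_unit: str, rmf: float):
    """Convert between linear/angular lengths and densities via the RMF.

    ``rmf`` is the retinal magnification factor in µm/degree.  Supported
    units: ``um`` ↔ ``deg`` and ``cones_per_mm2`` ↔ ``cones_per_deg2``.
    """
    if rmf <= 0:
        raise ValueError("rmf must be > 0")
    value = np.asarray(value, dtype=float)
    if from_unit == to_unit:
        out = value
    elif from_unit in _LENGTHS and to_unit in _LENGTHS:
        out = value / rmf if to_unit == "deg" else value * rmf
    elif from_unit in _DENSITIES and to_unit in _DENSITIES:
        mm_per_deg = rmf / 1000.0
        out = value * mm_per_deg**2 if to_unit == "cones_per_deg2" else value / mm_per_deg**2
    else:
        raise ValueError(f"unsupported conversion {from_unit} -> {to_unit}")
    return float(out) if out.ndim == 0 else out


def profile_slope_metrics(
    obj: Union[SigmoidParams, SigmoidFitResults, DensityProfile],
    max_ecc: float = 400.0,
    step: float = 0.01,
) -> Tuple[float, float]:
    """Maximum (most negative) density slope and its eccentricity.

    Computed by numerical differentiation (0.01 µm step) of the fitted
    sigmoid model.  A raw profile is fitted first and must be dense
    enough (≥ 10 distinct bins).
    """
    if isinstance(obj, SigmoidFitResults):
        params = obj.params
    elif isinstance(obj, SigmoidParams):
        params = obj
    elif isinstance(obj, DensityProfile):
        params = SigmoidDecayModel.from_profile(obj).fit().params
    else:
        raise TypeError(f"cannot derive slope metrics from {type(obj)!r}")
    return params.slope_metrics(max_ecc=max_ecc, step=step)
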