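"""Cohort orchestration: per-eye analysis and cohort summaries.

Runs the full chain for each eye — density map, topography metrics,
meridional/radial profiles, sigmoid fits, rugosity — and aggregates
cohort statistics (means/SDs, fellow-eye R² when eyes are paired).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.stats import linregress

from .density import (
    DEFAULT_K,
    TopographyMetrics,
    compute_cdc,
    compute_density_map,
    cones_in_region,
)
from .mosaic import ConeMosaic, read_mosaic
from .profiles import circular_profile, meridional_profile, radial_profile
from .rugosity import DEFAULT_RUGOSITY_ECCENTRICITIES, analyze_circular_profile
from .sigmoid import SigmoidFitResults, fit_profile

logger = logging.getLogger("conetopo")

__all__ = ["RunConfig", "EyeResult", "CohortSummary", "analyze_eye",
           "run_pipeline", "metric_correlation"]


@dataclass
class RunConfig:
    """Pipeline configuration with the standard analysis defaults."""

    inputs: List[str] = field(default_factory=list)
    grid_spacing: float = 1.0
    k: int = DEFAULT_K
    vertex_angle: float = 5.0
    ring_width: float = 50.0
    occlusion_radii: Tuple[float, ...] = (25.0, 75.0, 125.0, 175.0)
    rugosity_eccentricities: Tuple[float, ...] = DEFAULT_RUGOSITY_ECCENTRICITIES
    rmf_default: float = 291.0
    map_extent: Optional[float] = None
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.grid_spacing <= 0 or self.vertex_angle <= 0 or self.ring_width <= 0:
            raise ValueError("numeric config fields must be positive")
        if self.k < 3:
            raise ValueError("k must be >= 3")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class EyeResult:
    """Per-eye analysis artifacts."""

    name: str
    metrics: TopographyMetrics
    radial_fit: SigmoidFitResults
    horizontal_fit: SigmoidFitResults
    vertical_fit: SigmoidFitResults
    cone_counts: Dict[str, int]
    rugosity: Dict[float, Optional[float]]

    def summary_row(self) -> dict:
        slope_h, infl_h = self.horizontal_fit.slope_metrics()
        slope_v, infl_v = self.vertical_fit.slope_metrics()
        return {
            "eye": self.name,
            "d0": self.metrics.d0,
            "pcd": self.metrics.pcd,
            "isoa_top20": self.metrics.isoa_top20,
            "crossing50_radial": self.radial_fit.fraction_crossing(0.5),
            "max_slope_horizontal": slope_h,
            "max_slope_vertical": slope_v,
            "inflection_horizontal": infl_h,
            "inflection_vertical": infl_v,
            **{f"cones_{k}": v for k, v in self.cone_counts.items()},
        }


@dataclass
class CohortSummary:
    """Cohort-level aggregation of per-eye metrics."""

    eyes: List[EyeResult]
    means: Dict[str, float]
    sds: Dict[str, float]
    fellow_eye_r2: Dict[str, float] = field(default_factory=dict)


def analyze_eye(
    mosaic: ConeMosaic, config: RunConfig, name: str = "eye"
) -> EyeResult:
    """Run the single-eye analysis chain on one mosaic."""
    logger.info("analyzing %s: %d cones", name, len(mosaic))
    dmap = compute_density_map(
        mosaic, grid_spacing=config.grid_spacing, extent=config.map_extent,
        k=config.k,
    )
    metrics = compute_cdc(dmap)
    cdc = metrics.cdc_location

    radial = radial_profile(dmap, cdc)
    horizontal = meridional_profile(
        dmap, cdc, "horizontal", vertex_angle=config.vertex_angle,
        laterality=mosaic.laterality,
    )
    vertical = meridional_profile(
        dmap, cdc, "vertical", vertex_angle=config.vertex_angle,
        laterality=mosaic.laterality,
    )
    radial_fit = fit_profile(radial, fix_d0=metrics.d0)
    horizontal_fit = fit_profile(horizontal, fix_d0=metrics.d0)
    vertical_fit = fit_profile(vertical, fix_d0=metrics.d0)

    counts = {
        "circle75": cones_in_region(mosaic, cdc, 0, 75),
        "ring1": cones_in_region(mosaic, cdc, 75, 150),
        "ring2": cones_in_region(mosaic, cdc, 150, 225),
    }

    rug: Dict[float, Optional[float]] = {}
    for ecc in config.rugosity_eccentricities:
        try:
            cp = circular_profile(dmap, cdc, ecc, laterality=mosaic.laterality)
        except ValueError:
            continue
        cp.density = cp.density / metrics.d0  # D0-normalized before analysis
        cp.normalized = True
        rug[float(ecc)] = analyze_circular_profile(cp).rugosity

    return EyeResult(
        name=name,
        metrics=metrics,
        radial_fit=radial_fit,
        horizontal_fit=horizontal_fit,
        vertical_fit=vertical_fit,
        cone_counts=counts,
        rugosity=rug,
    )


def metric_correlation(x, y) -> float:
    """Coefficient of determination R² of the OLS fit of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x has no defined correlation")
    return float(linregress(x, y).rvalue ** 2)


def run_pipeline(
    config: RunConfig,
    mosaics: Optional[Sequence[ConeMosaic]] = None,
    names: Optional[Sequence[str]] = None,
    pairs: Optional[Sequence[Tuple[int, int]]] = None,
) -> CohortSummary:
    """Analyze a cohort of mosaics and aggregate cohort statistics.

    Mosaics come either from ``config.inputs`` (CSV paths) or directly as
    objects.  Per-eye failures are isolated: the eye is logged and
    skipped, the cohort continues.  ``pairs`` lists (left, right) index
    pairs for fellow-eye R² of D0 and derived metrics.
    """
    logging.basicConfig(level=config.log_level)
    if mosaics is None:
        mosaics = [read_mosaic(p) for p in config.inputs]
        names = names or [Path(p).stem for p in config.inputs]
    names = list(names or (f"eye{i}" for i in range(len(mosaics))))
    logger.info("pipeline start: %d eyes, config %s", len(mosaics), config.config_hash())

    eyes: List[EyeResult] = []
    for mosaic, name in zip(mosaics, names):
        try:
            eyes.append(analyze_eye(mosaic, config, name=name))
        except Exception:
            logger.exception("eye %s failed; continuing", name)
    if not eyes:
        raise ValueError("no eye analyzed successfully")

    rows = [e.summary_row() for e in eyes]
    keys = [k for k in rows[0] if k != "eye"]
    means = {k: float(np.mean([r[k] for r in rows])) for k in keys}
    sds = {k: float(np.std([r[k] for r in rows], ddof=1)) if len(rows) > 1 else 0.0
           for k in keys}

    fellow_r2: Dict[str, float] = {}
    if pairs:
        name_index = {e.name: i for i, e in enumerate(eyes)}
        usable = [
            (i, j) for i, j in pairs
            if names[i] in name_index and names[j] in name_index
        ]
        if len(usable) >= 3:
            for key in ("d0", "pcd", "cones_circle75", "cones_ring1", "cones_ring2"):
                left = [rows[name_index[names[i]]][key] for i, j in usable]
                right = [rows[name_index[names[j]]][key] for i, j in usable]
                fellow_r2[key] = metric_correlation(left, right)

    summary = CohortSummary(eyes=eyes, means=means, sds=sds, fellow_eye_r2=fellow_r2)
    logger.info("pipeline done: %d eyes analyzed", len(eyes))
    return summary
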