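"""Cone mosaic container and CSV/JSON round-trip I/O.

A :class:`ConeMosaic` is the universal input of the pipeline: annotated
cone center coordinates in µm on the retina, plus per-eye metadata (the
retinal magnification factor, laterality and an optional central occlusion
radius).  On disk a mosaic is a two-column CSV (``x_um,y_um``) with a JSON
metadata sidecar next to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["ConeMosaic", "read_mosaic", "write_mosaic", "DEFAULT_RMF"]

#: Emmetropic retinal magnification factor, µm of retina per degree of
#: visual angle; used when no per-eye biometry metadata is available.
DEFAULT_RMF = 291.0

_LATERALITIES = ("OS", "OD", "synthetic")


@dataclass
class ConeMosaic:
    """Planar cone center annotations with per-eye metadata.

    Attributes
    ----------
    coordinates : (n, 2) ndarray
        Cone centers in µm, relative to an arbitrary origin.  Retinal
        image convention: +y is superior; +x is nasal for left eyes (OS)
        and for synthetic mosaics, temporal for right eyes (OD).
    rmf : float
        Retinal magnification factor, µm/degree.
    laterality : str
        One of ``OS``, ``OD``, ``synthetic``.
    occlusion_radius : float or None
        When set, no cone lies strictly inside the central disk of this
        radius (µm) around the occlusion center.
    occlusion_center : (float, float)
        Center of the occluded disk (µm); only meaningful with
        ``occlusion_radius``.
    provenance : str
        Free-text origin note (generator config, source file, ...).
    """

    coordinates: np.ndarray
    rmf: float = DEFAULT_RMF
    laterality: str = "synthetic"
    occlusion_radius: Optional[float] = None
    occlusion_center: Tuple[float, float] = (0.0, 0.0)
    provenance: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coordinates must be an (n, 2) array")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must all be finite")
        if np.unique(coords, axis=0).shape[0] != coords.shape[0]:
            raise ValueError("duplicate cone coordinates are not allowed")
        if self.rmf <= 0:
            raise ValueError("rmf must be > 0")
        if self.laterality not in _LATERALITIES:
            raise ValueError(f"laterality must be one of {_LATERALITIES}")
        if self.occlusion_radius is not None:
            if self.occlusion_radius < 0:
                raise ValueError("occlusion_radius must be >= 0")
            r = np.hypot(*(coords - np.asarray(self.occlusion_center)).T)
            if np.any(r < self.occlusion_radius - 1e-12):
                raise ValueError("cones found inside the declared occlusion disk")
        self.coordinates = coords

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_cones(self) -> int:
        return len(self)

    def occlude(
        self, radius: float, center: Tuple[float, float] = (0.0, 0.0)
    ) -> "ConeMosaic":
        """Remove all cones strictly inside the disk; returns a new mosaic.

        Emulates centrally unresolved imagery.  Rejects radii that leave
        fewer than 200 cones (too few for 150-nearest-cone density
        estimation).
        """
        if radius < 0:
            raise ValueError("occlusion radius must be >= 0")
        r = np.hypot(*(self.coordinates - np.asarray(center, float)).T)
        keep = r >= radius
        if keep.sum() < 200:
            raise ValueError(
                f"occlusion radius {radius} µm leaves {int(keep.sum())} cones "
                "(< 200 required)"
            )
        return ConeMosaic(
            coordinates=self.coordinates[keep].copy(),
            rmf=self.rmf,
            laterality=self.laterality,
            occlusion_radius=float(radius),
            occlusion_center=(float(center[0]), float(center[1])),
            provenance=self.provenance,
        )

    def metadata(self) -> dict:
        return {
            "rmf_um_per_deg": self.rmf,
            "laterality": self.laterality,
            "occlusion_radius_um": self.occlusion_radius,
            "occlusion_center_um": list(self.occlusion_center),
            "provenance": self.provenance,
        }


def occlude_mosaic(
    mosaic: ConeMosaic, radius: float, center: Tuple[float, float] = (0.0, 0.0)
) -> ConeMosaic:
    """Functional alias of :meth:`ConeMosaic.occlude`."""
    return mosaic.occlude(radius, center)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_mosaic(mosaic: ConeMosaic, path) -> Path:
    """Write a mosaic as ``x_um,y_um`` CSV plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(mosaic.coordinates, columns=["x_um", "y_um"]).to_csv(
        path, index=False, float_format="%.6f"
    )
    _sidecar_path(path).write_text(json.dumps(mosaic.metadata(), indent=2))
    return path


def read_mosaic(path, warn_missing_sidecar: bool = True) -> ConeMosaic:
    """Read a mosaic CSV (+ optional JSON sidecar).

    Malformed or duplicate rows are rejected with their 1-based data line
    numbers; a missing sidecar falls back to defaults (RMF 291 µm/deg,
    synthetic laterality) with a warning.
    """
    import warnings

    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["x_um", "y_um"]:
        raise ValueError(f"{path}: expected header 'x_um,y_um', got {list(df.columns)}")
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(xy).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"{path}: malformed coordinate rows at data lines {bad + 1}")
    _, first, counts = np.unique(xy, axis=0, return_index=True, return_counts=True)
    if np.any(counts > 1):
        dup_rows = sorted(
            int(i) + 1
            for f, c in zip(first, counts)
            if c > 1
            for i in np.nonzero((xy == xy[f]).all(axis=1))[0][1:]
        )
        raise ValueError(f"{path}: duplicate coordinates at data lines {dup_rows}")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    elif warn_missing_sidecar:
        warnings.warn(f"{path}: no metadata sidecar found, using defaults")
    occ_center = meta.get("occlusion_center_um") or (0.0, 0.0)
    return ConeMosaic(
        coordinates=xy,
        rmf=float(meta.get("rmf_um_per_deg", DEFAULT_RMF)),
        laterality=meta.get("laterality", "synthetic"),
        occlusion_radius=meta.get("occlusion_radius_um"),
        occlusion_center=(float(occ_center[0]), float(occ_center[1])),
        provenance=meta.get("provenance", ""),
    )
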