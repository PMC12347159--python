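"""CSV/JSON serialization of maps, profiles, fits and references.

Everything is plain text: density maps are CSV grids with a JSON geometry
sidecar, profiles are two-column CSV with a JSON sidecar carrying kind,
bin width and normalization state, fit results and normative references
are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityMap
from .profiles import DensityProfile
from .recovery import NormativeReference
from .sigmoid import SigmoidFitResults

__all__ = [
    "write_density_map", "read_density_map",
    "write_profile", "read_profile",
    "write_fit_results", "write_reference", "read_reference",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_density_map(dmap: DensityMap, path) -> Path:
    path = Path(path)
    pd.DataFrame(dmap.values).to_csv(path, index=False, header=False,
                                     float_format="%.4f", na_rep="nan")
    _sidecar(path).write_text(json.dumps({
        "grid_origin_um": list(dmap.grid_origin),
        "grid_spacing_um": dmap.grid_spacing,
        "shape": list(dmap.values.shape),
    }, indent=2))
    return path


def read_density_map(path) -> DensityMap:
    path = Path(path)
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    return DensityMap(
        values=values,
        grid_origin=tuple(meta["grid_origin_um"]),
        grid_spacing=float(meta["grid_spacing_um"]),
    )


def write_profile(profile: DensityProfile, path) -> Path:
    path = Path(path)
    value_col = (
        "normalized_density" if profile.normalized
        else ("icd_um" if profile.units == "um" else "density_cones_per_mm2")
    )
    pd.DataFrame({
        "eccentricity_um": profile.eccentricity,
        value_col: profile.density,
    }).to_csv(path, index=False, float_format="%.6f")
    _sidecar(path).write_text(json.dumps({
        "kind": profile.kind,
        "bin_width_um": profile.bin_width,
        "normalized": profile.normalized,
        "d0_ref_cones_per_mm2": profile.d0_ref,
        "units": profile.units,
    }, indent=2))
    return path


def read_profile(path) -> DensityProfile:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return DensityProfile(
        kind=meta.get("kind", "radial"),
        eccentricity=df.iloc[:, 0].to_numpy(dtype=float),
        density=df.iloc[:, 1].to_numpy(dtype=float),
        bin_width=float(meta.get("bin_width_um", np.median(np.diff(df.iloc[:, 0])))),
        normalized=bool(meta.get("normalized", False)),
        d0_ref=meta.get("d0_ref_cones_per_mm2"),
        units=meta.get("units", "cones_per_mm2"),
    )


def write_fit_results(results: SigmoidFitResults, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(results.as_dict(), indent=2))
    return path


def write_reference(reference: NormativeReference, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(reference.as_dict(), indent=2))
    return path


def read_reference(path) -> NormativeReference:
    return NormativeReference.from_dict(json.loads(Path(path).read_text()))
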