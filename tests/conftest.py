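"""Shared fixtures: synthetic mosaics, analytic density maps, lattices."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import conetopo as ct
from conetopo.density import DensityMap

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def hex_lattice(spacing: float, half_extent: float) -> np.ndarray:
    """Hexagonal lattice points filling a square of given half-extent."""
    dy = spacing * np.sqrt(3) / 2
    rows = np.arange(-int(half_extent / dy) - 1, int(half_extent / dy) + 2)
    cols = np.arange(-int(half_extent / spacing) - 1, int(half_extent / spacing) + 2)
    jj, ii = np.meshgrid(cols, rows)
    x = jj * spacing + (ii % 2) * (spacing / 2)
    y = ii * dy
    pts = np.column_stack([x.ravel(), y.ravel()])
    keep = (np.abs(pts[:, 0]) <= half_extent) & (np.abs(pts[:, 1]) <= half_extent)
    return pts[keep]


def square_lattice(spacing: float, half_extent: float) -> np.ndarray:
    axis = np.arange(-half_extent, half_extent + spacing / 2, spacing)
    xx, yy = np.meshgrid(axis, axis)
    return np.column_stack([xx.ravel(), yy.ravel()])


def map_from_field(field, extent: float, spacing: float = 1.0) -> DensityMap:
    """Analytic density map: evaluate ``field(x, y)`` on a regular grid."""
    axis = np.arange(-extent, extent + spacing / 2, spacing)
    xx, yy = np.meshgrid(axis, axis)
    return DensityMap(
        values=field(xx, yy),
        grid_origin=(float(axis[0]), float(axis[0])),
        grid_spacing=float(spacing),
    )


def radial_field(params: ct.SigmoidParams):
    def field(x, y):
        return params.d0 / (1.0 + (np.hypot(x, y) / params.a) ** params.b) ** params.c
    return field


@pytest.fixture(scope="session")
def default_mosaic() -> ct.ConeMosaic:
    """Normative anisotropic mosaic, 300 µm field, default jitter."""
    return ct.generate_mosaic(ct.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_map(default_mosaic) -> DensityMap:
    return ct.compute_density_map(default_mosaic, grid_spacing=2.0)


@pytest.fixture(scope="session")
def default_metrics(default_map):
    return ct.compute_cdc(default_map)


@pytest.fixture(scope="session")
def isotropic_config() -> ct.GeneratorConfig:
    triplet = (ct.NORMATIVE_RADIAL.a, ct.NORMATIVE_RADIAL.b, ct.NORMATIVE_RADIAL.c)
    return ct.GeneratorConfig(params_horizontal=triplet, params_vertical=triplet, seed=2)


@pytest.fixture(scope="session")
def isotropic_mosaic(isotropic_config) -> ct.ConeMosaic:
    return ct.generate_mosaic(isotropic_config)


@pytest.fixture(scope="session")
def isotropic_map(isotropic_mosaic) -> DensityMap:
    return ct.compute_density_map(isotropic_mosaic, grid_spacing=2.0)


@pytest.fixture(scope="session")
def isotropic_metrics(isotropic_map):
    return ct.compute_cdc(isotropic_map)


@pytest.fixture(scope="session")
def cohort57_loo():
    """57-eye synthetic cohort with leave-one-out occlusion recovery."""
    ecc, profiles, params = ct.cohort_radial_profiles(57, seed=11)
    d0s = [p.d0 for p in params]
    out = ct.leave_one_out_errors(profiles, d0s, truths=params)
    return out
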