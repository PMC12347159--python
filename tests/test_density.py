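"""Voronoi density estimation, density maps and topography metrics."""

import numpy as np
import pytest

import conetopo as ct
from conetopo.density import (
    DensityMap,
    VoronoiDensityEstimator,
    compute_cdc,
    cones_in_region,
    density_at_point,
    iso_density_contour_metrics,
    voronoi_cell_areas,
)
from conetopo.mosaic import ConeMosaic

from conftest import hex_lattice, map_from_field, radial_field, square_lattice

S_HEX = 2.54
HEX_DENSITY = 2.0 / (np.sqrt(3) * S_HEX**2) * 1e6  # cones/mm², closed form


@pytest.fixture(scope="module")
def hex_mosaic():
    return ConeMosaic(hex_lattice(S_HEX, 60.0))


@pytest.fixture(scope="module")
def square_mosaic():
    return ConeMosaic(square_lattice(2.5, 60.0))


class TestVoronoiCellAreas:
    def test_hexagonal_interior_cell_area(self, hex_mosaic):
        areas, unbounded = voronoi_cell_areas(hex_mosaic)
        r = np.hypot(*hex_mosaic.coordinates.T)
        interior = (~unbounded) & (r < 40)
        expected = np.sqrt(3) / 2 * S_HEX**2
        assert np.allclose(areas[interior], expected, rtol=1e-9)

    def test_square_interior_cell_area(self, square_mosaic):
        areas, unbounded = voronoi_cell_areas(square_mosaic)
        r = np.hypot(*square_mosaic.coordinates.T)
        interior = (~unbounded) & (r < 40)
        assert np.allclose(areas[interior], 2.5**2, rtol=1e-9)

    def test_hull_cells_flagged_unbounded(self, square_mosaic):
        areas, unbounded = voronoi_cell_areas(square_mosaic)
        corner = np.argmax(square_mosaic.coordinates.sum(axis=1))
        assert unbounded[corner]
        assert np.isnan(areas[corner])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            voronoi_cell_areas(np.array([[0, 0], [1, 1], [2, 2]], float))
        with pytest.raises(ValueError):
            voronoi_cell_areas(np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float))


class TestDensityAtPoint:
    def test_hexagonal_closed_form(self, hex_mosaic):
        d = density_at_point((0.3, 0.2), hex_mosaic)
        assert abs(d / HEX_DENSITY - 1) < 0.005

    def test_square_closed_form(self, square_mosaic):
        d = density_at_point((0.1, -0.4), square_mosaic)
        assert abs(d / 160_000.0 - 1) < 0.005

    def test_point_outside_reliable_region_invalid(self, square_mosaic):
        assert np.isnan(density_at_point((70.0, 0.0), square_mosaic))

    def test_estimator_requires_enough_cones(self):
        with pytest.raises(ValueError):
            VoronoiDensityEstimator(ConeMosaic(square_lattice(2.5, 10.0)), k=150)

    def test_scale_covariance(self):
        # coordinates ×λ ⇒ densities ×1/λ², cell areas ×λ²
        lam = 1.7
        base = ConeMosaic(hex_lattice(S_HEX, 50.0))
        scaled = ConeMosaic(base.coordinates * lam)
        d1 = density_at_point((1.0, 2.0), base, k=60)
        d2 = density_at_point((lam, 2 * lam), scaled, k=60)
        assert d2 == pytest.approx(d1 / lam**2, rel=1e-9)
        a1, u1 = voronoi_cell_areas(base)
        a2, _ = voronoi_cell_areas(scaled)
        assert np.allclose(a2[~u1], a1[~u1] * lam**2)


class TestDensityMap:
    def test_constant_mosaic_low_variation(self):
        from test_synthetic import CONSTANT_FIELD

        mosaic = ct.generate_mosaic(CONSTANT_FIELD)
        dmap = ct.compute_density_map(mosaic, grid_spacing=4.0)
        vals = dmap.values[dmap.valid_mask]
        assert vals.std() / vals.mean() < 0.03

    def test_map_maximum_near_config_d0(self, default_map):
        pcd = np.nanmax(default_map.values)
        assert abs(pcd / 175_500.0 - 1) < 0.05

    def test_occluded_center_still_estimable(self, default_mosaic):
        # cells around an interior hole stay bounded; center query is finite
        occluded = default_mosaic.occlude(50.0)
        d = density_at_point((0.0, 0.0), occluded)
        assert np.isfinite(d)
        assert d < 175_500.0

    def test_invalid_spacing_rejected(self, default_mosaic):
        with pytest.raises(ValueError):
            ct.compute_density_map(default_mosaic, grid_spacing=0.0)


class TestComputeCdc:
    def test_symmetric_map_centers_cdc_at_origin(self):
        dmap = map_from_field(radial_field(ct.NORMATIVE_RADIAL), 120, 1.0)
        met = compute_cdc(dmap)
        assert abs(met.cdc_location[0]) <= dmap.grid_spacing
        assert abs(met.cdc_location[1]) <= dmap.grid_spacing
        assert met.d0 <= met.pcd

    def test_translation_equivariance(self):
        field = radial_field(ct.NORMATIVE_RADIAL)
        dmap = map_from_field(field, 120, 1.0)
        shifted = map_from_field(lambda x, y: field(x - 37, y + 12), 120, 1.0)
        m0 = compute_cdc(dmap)
        m1 = compute_cdc(shifted)
        assert m1.cdc_location[0] - m0.cdc_location[0] == pytest.approx(37, abs=1e-6)
        assert m1.cdc_location[1] - m0.cdc_location[1] == pytest.approx(-12, abs=1e-6)

    def test_rotation_invariance_of_pcd_and_d0(self, default_mosaic, default_metrics):
        ang = np.radians(30)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = ConeMosaic(default_mosaic.coordinates @ rot.T)
        met = compute_cdc(ct.compute_density_map(rotated, grid_spacing=2.0))
        assert met.pcd == pytest.approx(default_metrics.pcd, rel=0.005)
        assert met.d0 == pytest.approx(default_metrics.d0, rel=0.005)

    def test_d0_not_above_pcd(self, default_metrics, isotropic_metrics):
        assert default_metrics.d0 <= default_metrics.pcd
        assert isotropic_metrics.d0 <= isotropic_metrics.pcd

    def test_empty_map_rejected(self):
        dmap = DensityMap(np.full((5, 5), np.nan), (0, 0), 1.0)
        with pytest.raises(ValueError):
            compute_cdc(dmap)


class TestIsoDensityContours:
    def test_isotropic_aspect_ratio_near_one(self):
        dmap = map_from_field(radial_field(ct.NORMATIVE_RADIAL), 150, 1.0)
        _, aspect = iso_density_contour_metrics(dmap, 0.6 * 175_500, (0.0, 0.0))
        assert aspect == pytest.approx(1.0, rel=0.05)

    def test_stretched_map_aspect_ratio(self):
        field = radial_field(ct.NORMATIVE_RADIAL)
        dmap = map_from_field(lambda x, y: field(x / 1.3, y), 200, 1.0)
        area, aspect = iso_density_contour_metrics(dmap, 0.6 * 175_500, (0.0, 0.0))
        assert aspect == pytest.approx(1.3, rel=0.03)
        # affine image: area scales by 1.3 vs the isotropic region
        iso = map_from_field(field, 200, 1.0)
        iso_area, _ = iso_density_contour_metrics(iso, 0.6 * 175_500, (0.0, 0.0))
        assert area == pytest.approx(1.3 * iso_area, rel=0.03)

    def test_level_above_peak_rejected(self):
        dmap = map_from_field(radial_field(ct.NORMATIVE_RADIAL), 100, 1.0)
        with pytest.raises(ValueError):
            iso_density_contour_metrics(dmap, 2e5, (0.0, 0.0))


class TestConesInRegion:
    def test_full_disk_counts_everything(self, default_mosaic):
        n = cones_in_region(default_mosaic, (0, 0), 0, np.inf)
        assert n == len(default_mosaic)

    def test_hexagonal_disk_count_matches_area_density(self, hex_mosaic):
        r = 10 * S_HEX
        n = cones_in_region(hex_mosaic, (0, 0), 0, r)
        expected = np.pi * r**2 * HEX_DENSITY * 1e-6
        assert n == pytest.approx(expected, rel=0.05)

    def test_ring_additivity(self, default_mosaic):
        c = (0.0, 0.0)
        total = cones_in_region(default_mosaic, c, 0, 225)
        parts = (
            cones_in_region(default_mosaic, c, 0, 75)
            + cones_in_region(default_mosaic, c, 75, 150)
            + cones_in_region(default_mosaic, c, 150, 225)
        )
        assert parts == total

    def test_invalid_radii_rejected(self, default_mosaic):
        with pytest.raises(ValueError):
            cones_in_region(default_mosaic, (0, 0), 50, 50)
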