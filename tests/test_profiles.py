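"""Profile extraction, unit conversion and slope metrics."""

import numpy as np
import pytest

import conetopo as ct
from conetopo.mosaic import ConeMosaic
from conetopo.profiles import (
    circular_profile,
    convert_units,
    intercone_distance_profile,
    meridional_profile,
    normalize_profile,
    profile_slope_metrics,
    radial_profile,
    retinal_to_image_angle,
)

from conftest import hex_lattice, map_from_field, radial_field

S_HEX = 2.54


@pytest.fixture(scope="module")
def analytic_map():
    return map_from_field(radial_field(ct.NORMATIVE_RADIAL), 150, 1.0)


class TestMeridionalProfiles:
    def test_isotropic_map_horizontal_equals_vertical(self, analytic_map):
        h = meridional_profile(analytic_map, (0, 0), "horizontal")
        v = meridional_profile(analytic_map, (0, 0), "vertical")
        n = min(h.density.size, v.density.size)
        rms = np.sqrt(np.mean((h.density[:n] / v.density[:n] - 1) ** 2))
        assert rms < 0.03

    def test_measured_horizontal_crossing_near_printed_value(
        self, default_map, default_metrics
    ):
        # anisotropic normative mosaic: horizontal meridian halves near 171 µm
        h = meridional_profile(
            default_map, default_metrics.cdc_location, "horizontal"
        )
        fit = ct.fit_profile(h, fix_d0=default_metrics.d0)
        assert fit.fraction_crossing(0.5) == pytest.approx(171.1, rel=0.03)

    def test_quadrants_average_to_meridian(self, analytic_map):
        nas = meridional_profile(analytic_map, (0, 0), "nasal")
        tem = meridional_profile(analytic_map, (0, 0), "temporal")
        hor = meridional_profile(analytic_map, (0, 0), "horizontal")
        n = min(nas.density.size, tem.density.size, hor.density.size)
        pairwise = (nas.density[:n] + tem.density[:n]) / 2
        assert np.allclose(pairwise, hor.density[:n], rtol=0.01)

    def test_cdc_outside_map_rejected(self, analytic_map):
        with pytest.raises(ValueError):
            meridional_profile(analytic_map, (500, 0), "horizontal")


class TestRadialAndCircular:
    def test_radial_profile_starts_at_d0(self, analytic_map):
        r = radial_profile(analytic_map, (0, 0))
        assert r.eccentricity[0] == 0.0
        assert r.density[0] == pytest.approx(175_500.0, rel=1e-6)

    def test_radial_crossing_matches_model(self, analytic_map):
        r = radial_profile(analytic_map, (0, 0))
        half = np.interp(0.5 * 175_500, r.density[::-1], r.eccentricity[::-1])
        assert half == pytest.approx(151.35, rel=0.01)

    def test_radial_equals_meridional_on_isotropic_map(self, analytic_map):
        r = radial_profile(analytic_map, (0, 0))
        h = meridional_profile(analytic_map, (0, 0), "horizontal")
        n = min(r.density.size, h.density.size)
        assert np.allclose(r.density[:n], h.density[:n], rtol=0.02)

    def test_circular_profile_constant_on_isotropic_map(self, analytic_map):
        cp = circular_profile(analytic_map, (0, 0), 90.0)
        assert cp.density.std() / cp.density.mean() < 0.02

    def test_radial_is_angular_mean_of_circular(self, analytic_map):
        r = radial_profile(analytic_map, (0, 0))
        for ecc in (40.0, 90.0, 130.0):
            cp = circular_profile(analytic_map, (0, 0), ecc)
            i = int(np.argmin(np.abs(r.eccentricity - ecc)))
            assert cp.density.mean() == pytest.approx(r.density[i], rel=0.01)

    def test_cos2theta_modulated_map_extrema_positions(self):
        field = radial_field(ct.NORMATIVE_RADIAL)
        dmap = map_from_field(
            lambda x, y: field(x, y) * (1 + 0.2 * np.cos(2 * np.arctan2(y, x))),
            150, 1.0,
        )
        cp = circular_profile(dmap, (0, 0), 100.0)
        assert cp.theta[np.argmax(cp.density)] in (0.0, 180.0)
        assert cp.theta[np.argmin(cp.density)] in (90.0, 270.0)

    def test_circle_exiting_valid_region_rejected(self, analytic_map):
        with pytest.raises(ValueError):
            circular_profile(analytic_map, (0, 0), 500.0)

    def test_od_laterality_mirrors_nasal_direction(self):
        assert retinal_to_image_angle(0.0, "OD") == 180.0
        assert retinal_to_image_angle(90.0, "OD") == 90.0
        assert retinal_to_image_angle(0.0, "OS") == 0.0


class TestNormalize:
    def test_normalized_center_is_one(self, analytic_map):
        r = radial_profile(analytic_map, (0, 0))
        norm = normalize_profile(r, r.density[0])
        assert norm.density[0] == pytest.approx(1.0)
        assert norm.normalized and norm.d0_ref == r.density[0]

    def test_roundtrip_and_linearity(self, analytic_map):
        r = radial_profile(analytic_map, (0, 0))
        norm = normalize_profile(r, 175_500.0)
        assert np.allclose(norm.density * 175_500.0, r.density, rtol=1e-12)

    def test_double_normalization_rejected(self, analytic_map):
        r = radial_profile(analytic_map, (0, 0))
        norm = normalize_profile(r, 175_500.0)
        with pytest.raises(ValueError):
            normalize_profile(norm, 175_500.0)
        with pytest.raises(ValueError):
            normalize_profile(r, -1.0)


class TestInterconeDistance:
    def test_hexagonal_lattice_icd_equals_spacing(self):
        mosaic = ConeMosaic(hex_lattice(S_HEX, 40.0))
        prof = intercone_distance_profile(mosaic, (0, 0))
        interior = prof.eccentricity < 25
        assert np.allclose(prof.density[interior], S_HEX, rtol=0.02)
        assert prof.units == "um"

    def test_icd_scales_with_coordinates(self):
        lam = 2.3
        base = ConeMosaic(hex_lattice(S_HEX, 40.0))
        scaled = ConeMosaic(base.coordinates * lam)
        p1 = intercone_distance_profile(base, (0, 0))
        p2 = intercone_distance_profile(scaled, (0, 0), bin_width=2.0 * lam)
        assert p2.density[0] == pytest.approx(lam * p1.density[0], rel=0.02)

    def test_icd_matches_hexagonal_density_relation(self, default_mosaic, default_metrics):
        # ICD ≈ sqrt(2/(√3·D)) on locally hexagonal mosaics
        prof = intercone_distance_profile(default_mosaic, default_metrics.cdc_location)
        d0_um2 = default_metrics.d0 * 1e-6
        expected = np.sqrt(2.0 / (np.sqrt(3.0) * d0_um2))
        central = prof.eccentricity < 20
        assert np.allclose(prof.density[central], expected, rtol=0.05)


class TestConvertUnits:
    def test_degree_to_micron(self):
        assert convert_units(1.0, "deg", "um", rmf=291.0) == 291.0

    def test_linear_to_angular_density(self):
        out = convert_units(175_500.0, "cones_per_mm2", "cones_per_deg2", rmf=291.0)
        assert out == pytest.approx(14_861.5, abs=0.5)

    def test_roundtrip_identity(self):
        x = 123.456
        back = convert_units(
            convert_units(x, "um", "deg", 291.0), "deg", "um", 291.0
        )
        assert back == pytest.approx(x, rel=1e-14)

    def test_unsupported_pair_rejected(self):
        with pytest.raises(ValueError):
            convert_units(1.0, "um", "cones_per_mm2", 291.0)
        with pytest.raises(ValueError):
            convert_units(1.0, "um", "deg", -291.0)


class TestSlopeMetrics:
    def test_radial_model_slope_and_inflection(self):
        # brute-force 0.01 µm differentiation of the normative radial model
        slope, infl = profile_slope_metrics(ct.NORMATIVE_RADIAL)
        assert slope == pytest.approx(-877.9, rel=0.005)
        assert infl == pytest.approx(52.5, abs=0.5)

    def test_doubling_d0_doubles_slope_same_inflection(self):
        p = ct.NORMATIVE_RADIAL
        doubled = ct.SigmoidParams(2 * p.d0, p.a, p.b, p.c)
        s1, e1 = profile_slope_metrics(p)
        s2, e2 = profile_slope_metrics(doubled)
        assert s2 == pytest.approx(2 * s1, rel=1e-9)
        assert e2 == e1

    def test_profile_input_is_fitted_first(self, analytic_map):
        r = radial_profile(analytic_map, (0, 0))
        slope, infl = profile_slope_metrics(r)
        assert slope == pytest.approx(-877.9, rel=0.03)
        with pytest.raises(ValueError):
            profile_slope_metrics(
                ct.DensityProfile("radial", np.arange(5.0), np.linspace(2e5, 1e5, 5), 1.0)
            )
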