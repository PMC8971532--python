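"""Idealized biventricular geometry, features, fibers, equivalent cylinder."""

import math

import numpy as np
import pytest

import myostiff as ms
from myostiff.anatomy import (DEFAULT_PARENT_RANGES, RV_AXIAL_EXTENT,
                              CylinderModel, ParentGeometry, equivalent_cylinder,
                              fiber_layers, geometric_features, make_parent,
                              make_parent_library, resize)


class TestParentGeneration:
    def test_same_seed_same_parent(self):
        assert make_parent(123) == make_parent(123)

    def test_degenerate_range_pins_field(self):
        ranges = dict(DEFAULT_PARENT_RANGES)
        ranges["R_epi"] = (4.0, 4.0)
        ps = [make_parent(s, ranges) for s in range(10)]
        assert all(p.R_epi == 4.0 for p in ps)

    def test_inverted_range_rejected(self):
        ranges = dict(DEFAULT_PARENT_RANGES)
        ranges["Z_epi"] = (14.0, 11.0)
        with pytest.raises(ValueError):
            make_parent(0, ranges)

    def test_library_is_deterministic_and_distinct(self):
        lib1 = make_parent_library(25, seed=4)
        lib2 = make_parent_library(25, seed=4)
        assert lib1 == lib2
        assert len({p.R_lv for p in lib1}) == 25

    def test_unloaded_lv_volume_span(self, parents):
        """Across 25 parents x f_LV sweep, LV_V runs from ~35 ul to ~5x that."""
        vols = []
        for p in parents:
            for f in (0.7, 1.0, 1.3, 1.6):
                vols.append(geometric_features(resize(p, f, 1.0)).LV_V)
        lo, hi = min(vols), max(vols)
        assert 35.0 * 0.8 <= lo <= 35.0 * 1.2
        assert 5 * 35.0 * 0.8 <= hi <= 5 * 35.0 * 1.2


class TestResize:
    def test_identity_resize_preserves_features(self, parents):
        f0 = geometric_features(resize(parents[0], 1.0, 1.0))
        np.testing.assert_allclose(
            f0.to_array(),
            geometric_features(ms.HeartGeometry(parents[0])).to_array())

    def test_lv_volume_scales_quadratically(self, parents):
        # X-Y-plane-only scaling: volume of the ellipsoidal cap goes as f^2
        base = geometric_features(resize(parents[1], 1.0, 1.0))
        up = geometric_features(resize(parents[1], 1.1, 1.0))
        assert up.LV_V == pytest.approx(1.1 ** 2 * base.LV_V, rel=1e-12)

    def test_epicardium_invariant_under_resizing(self, parents):
        a = geometric_features(resize(parents[2], 0.8, 0.9))
        b = geometric_features(resize(parents[2], 1.5, 1.4))
        assert a.Epi_V == pytest.approx(b.Epi_V, rel=1e-14)
        assert a.Epi_A == pytest.approx(b.Epi_A, rel=1e-14)
        np.testing.assert_allclose(a.S_A, b.S_A, rtol=1e-14)

    def test_lv_features_monotone_in_flv(self, parents):
        vols = [geometric_features(resize(parents[3], f, 1.0)).LV_V
                for f in (0.7, 0.9, 1.1, 1.3, 1.5)]
        areas = [geometric_features(resize(parents[3], f, 1.0)).LV_A
                 for f in (0.7, 0.9, 1.1, 1.3, 1.5)]
        assert np.all(np.diff(vols) > 0)
        assert np.all(np.diff(areas) > 0)

    def test_endocardium_exiting_epicardium_rejected(self):
        tight = ParentGeometry(R_epi=3.0, Z_epi=12.0, R_lv=2.5, Z_lv=9.0,
                               rv_sector=1.5, rv_thickness_frac=0.4)
        with pytest.raises(ValueError):
            resize(tight, 1.6, 1.0)


class TestGeometricFeatures:
    def test_hemisphere_closed_forms(self):
        p = ParentGeometry(R_epi=10.0, Z_epi=10.0, R_lv=2.0, Z_lv=5.0,
                           rv_sector=1.0, rv_thickness_frac=0.3)
        f = geometric_features(ms.HeartGeometry(p))
        assert f.Epi_V == pytest.approx(2 / 3 * math.pi * 1000.0, rel=1e-9)
        assert f.Epi_A == pytest.approx(2 * math.pi * 100.0, rel=1e-9)  # lateral surface

    def test_basal_slice_is_equatorial_disc(self, parents):
        p = parents[0]
        f = geometric_features(ms.HeartGeometry(p))
        assert f.S_A[0] == pytest.approx(math.pi * p.R_epi ** 2, rel=1e-12)

    def test_slice_areas_decrease_toward_apex(self, parents):
        for p in parents[:10]:
            f = geometric_features(ms.HeartGeometry(p))
            assert np.all(np.diff(f.S_A) < 0)

    def test_volumes_against_monte_carlo(self, parents):
        """Quadrature features match rejection-sampling estimates within 0.5%."""
        rng = np.random.default_rng(9)
        for p in parents[:3]:
            geom = resize(p, rng.uniform(0.8, 1.5), rng.uniform(0.8, 1.5))
            f = geometric_features(geom)
            n = 400_000
            # sample the bounding cylinder of the epicardial half-ellipsoid
            r = p.R_epi * np.sqrt(rng.uniform(0, 1, n))
            phi = rng.uniform(0, 2 * math.pi, n)
            z = rng.uniform(0, p.Z_epi, n)
            box = math.pi * p.R_epi ** 2 * p.Z_epi
            inside_epi = r <= geom.r_epi(z)
            assert f.Epi_V == pytest.approx(box * inside_epi.mean(), rel=5e-3)
            inside_lv = (z <= p.Z_lv) & (r <= geom.r_lv(z))
            assert f.LV_V == pytest.approx(box * inside_lv.mean(), rel=5e-3)
            t = p.rv_thickness_frac * geom.f_RV
            inside_rv = ((z <= RV_AXIAL_EXTENT * p.Z_epi) & inside_epi
                         & (r >= (1 - t) * geom.r_epi(z))
                         & (phi <= p.rv_sector))
            assert f.RV_V == pytest.approx(box * inside_rv.mean(), rel=2e-2)

    def test_areas_against_dense_mesh(self, parents):
        """Quadrature areas match a fine surface-of-revolution discretization."""
        p = parents[4]
        geom = resize(p, 1.2, 1.1)
        f = geometric_features(geom)
        t = np.linspace(0, math.pi / 2, 40001)
        for R, Z, target in ((geom.lv_radius, p.Z_lv, f.LV_A),
                             (p.R_epi, p.Z_epi, f.Epi_A)):
            r = R * np.cos(t)
            z = Z * np.sin(t)
            seg = np.hypot(np.diff(r), np.diff(z))
            area = float(np.sum(2 * math.pi * 0.5 * (r[1:] + r[:-1]) * seg))
            assert target == pytest.approx(area, rel=5e-5)


class TestFiberLayers:
    def test_four_layer_symmetric_rule(self):
        fib = fiber_layers(math.pi / 3, -math.pi / 3, 4)
        np.testing.assert_allclose(np.rad2deg(fib.layer_angles),
                                   [45.0, 15.0, -15.0, -45.0], atol=1e-12)

    def test_antisymmetric_about_midwall(self):
        for n in (2, 3, 4, 7):
            fib = fiber_layers(0.8, -0.8, n)
            np.testing.assert_allclose(fib.layer_angles,
                                       -np.asarray(fib.layer_angles)[::-1],
                                       atol=1e-15)

    def test_two_layer_hand_values(self):
        fib = fiber_layers(0.9, -0.3, 2)
        np.testing.assert_allclose(fib.layer_angles, [0.6, 0.0], atol=1e-15)

    def test_sign_constraints_enforced(self):
        with pytest.raises(ValueError):
            fiber_layers(-0.1, -0.5)
        with pytest.raises(ValueError):
            fiber_layers(0.5, 0.1)


class TestEquivalentCylinder:
    def test_inner_radius_inverts_lumen_volume(self, parents):
        geom = resize(parents[0], 1.0, 1.0)
        f = geometric_features(geom)
        cyl = equivalent_cylinder(geom, f)
        assert cyl.lumen_volume == pytest.approx(f.LV_V, rel=1e-12)
        assert cyl.wall_volume == pytest.approx(f.Epi_V - f.LV_V - f.RV_V, rel=1e-12)
        assert cyl.L == parents[0].Z_epi

    def test_exact_closed_form_inversion(self):
        # lumen pi * 10^2 * 15 with L = 15 must give R_i = 10 exactly
        p = ParentGeometry(R_epi=30.0, Z_epi=15.0,
                           R_lv=15.0, Z_lv=10.0,  # cap volume (2/3) pi 225 * 10 = 1500 pi
                           rv_sector=1.0, rv_thickness_frac=0.3)
        geom = ms.HeartGeometry(p)
        f = geometric_features(geom)
        cyl = equivalent_cylinder(geom, f)
        assert f.LV_V == pytest.approx(math.pi * 10.0 ** 2 * 15.0, rel=1e-12)
        assert cyl.R_i == pytest.approx(10.0, rel=1e-12)

    def test_inner_radius_monotone_in_flv(self, parents):
        cyls = [equivalent_cylinder(resize(parents[5], f, 1.0))
                for f in (0.8, 1.0, 1.2, 1.4)]
        ri = [c.R_i for c in cyls]
        assert np.all(np.diff(ri) > 0)
        # R_o^2 = (Epi_V - RV_V)/(pi L) is independent of the LV resize factor
        ro = [c.R_o for c in cyls]
        assert np.ptp(ro) / ro[0] < 1e-9

    def test_invalid_cylinder_rejected(self):
        with pytest.raises(ValueError):
            CylinderModel(2.0, 1.0, 10.0)


def test_parent_library_roundtrip(tmp_path, parents):
    path = tmp_path / "parents.csv"
    ms.anatomy.write_parent_library(parents, path)
    back = ms.anatomy.read_parent_library(path)
    assert len(back) == len(parents)
    for a, b in zip(parents, back):
        assert a.R_epi == pytest.approx(b.R_epi, rel=1e-15)
        assert a.parent_id == b.parent_id
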