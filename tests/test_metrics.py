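"""Metric oracles: SSR closed forms, exact integrals, localization symmetry."""

import numpy as np
import pytest

from laa_stasis.centerline import Centerline, extract_centerline
from laa_stasis.errors import FieldError, InterpolationError, RegionError
from laa_stasis.meshing import Mesh, triangulate_domain
from laa_stasis.metrics import (
    centerline_profile,
    dye_localization,
    normalized_volume_integral,
    periodicity_metric,
    residual_contrast,
    ssr_field,
)


def _laa_rect_mesh(length=2.0, width=0.4, h=0.1):
    segs = [("wall", np.array([[0, 0], [length, 0], [length, width],
                               [0, width], [0, 0]], float))]
    mesh = triangulate_domain(segs, h)
    mesh.region = np.where(mesh.cell_centroids[:, 0] < 0.5 * length, "LAA", "LA")
    return mesh


class TestSSR:
    def test_uniform_flow_zero(self, unit_square_mesh):
        m = unit_square_mesh
        u = np.full(m.n_vertices, 2.5)
        v = np.full(m.n_vertices, -1.0)
        np.testing.assert_allclose(ssr_field(u, v, m), 0.0, atol=1e-10)

    def test_simple_shear_equals_gamma(self, unit_square_mesh):
        m = unit_square_mesh
        gamma = 3.7
        u = gamma * m.vertices[:, 1]
        v = np.zeros(m.n_vertices)
        np.testing.assert_allclose(ssr_field(u, v, m), gamma, rtol=1e-10)

    def test_rigid_rotation_zero(self, unit_square_mesh):
        m = unit_square_mesh
        om = 4.0
        u = -om * (m.vertices[:, 1] - 0.5)
        v = om * (m.vertices[:, 0] - 0.5)
        np.testing.assert_allclose(ssr_field(u, v, m), 0.0, atol=1e-9)

    def test_invariant_under_uniform_velocity_shift(self, unit_square_mesh):
        m = unit_square_mesh
        rng = np.random.default_rng(3)
        u = rng.normal(size=m.n_vertices)
        v = rng.normal(size=m.n_vertices)
        base = ssr_field(u, v, m)
        shifted = ssr_field(u + 5.0, v - 2.0, m)
        np.testing.assert_allclose(base, shifted, atol=1e-9)


class TestNormalizedVolumeIntegral:
    def test_constant_field(self, two_triangle_mesh):
        f_cell = np.array([4.2, 4.2])
        for region in ("LA", "LAA", "domain"):
            assert normalized_volume_integral(f_cell, two_triangle_mesh, region) == pytest.approx(4.2)

    def test_linear_field_exact_simplex_quadrature(self):
        """Mean of f=x over the unit right triangle is 1/3 (exact)."""
        mesh = Mesh(
            vertices=np.array([[0, 0], [1, 0], [0, 1]], float),
            cells=np.array([[0, 1, 2]]),
            boundary_edges=np.array([[0, 1], [1, 2], [2, 0]]),
            boundary_labels=np.array(["wall"] * 3),
            region=np.array(["LAA"]),
            h=1.0,
        )
        f = mesh.vertices[:, 0]
        assert normalized_volume_integral(f, mesh, "LAA") == pytest.approx(1.0 / 3.0)

    def test_linearity_and_bounds(self, unit_square_mesh):
        m = unit_square_mesh
        rng = np.random.default_rng(7)
        f = rng.uniform(1.0, 2.0, m.n_vertices)
        g = rng.uniform(-1.0, 0.0, m.n_vertices)
        a = normalized_volume_integral(f, m, "domain")
        b = normalized_volume_integral(g, m, "domain")
        combo = normalized_volume_integral(2 * f + g, m, "domain")
        assert combo == pytest.approx(2 * a + b, rel=1e-12)
        assert f.min() <= a <= f.max()

    def test_empty_region_raises(self, unit_square_mesh):
        with pytest.raises(RegionError):
            normalized_volume_integral(np.zeros(unit_square_mesh.n_cells),
                                       unit_square_mesh, "LAA")


class TestResidualContrast:
    def test_uniform_one_is_100(self, two_triangle_mesh):
        c = np.ones(2)
        assert residual_contrast(c, two_triangle_mesh, "domain") == pytest.approx(100.0)

    def test_zero_is_zero(self, two_triangle_mesh):
        assert residual_contrast(np.zeros(2), two_triangle_mesh, "domain") == 0.0

    def test_laa_only_dye(self, two_triangle_mesh):
        """c=1 on the LAA half: domain-normalized = 100*V_LAA/V_domain."""
        c = np.array([0.0, 1.0])  # cell 1 is LAA
        assert residual_contrast(c, two_triangle_mesh, "domain") == pytest.approx(50.0)
        assert residual_contrast(c, two_triangle_mesh, "laa") == pytest.approx(100.0)

    def test_out_of_bounds_raises(self, two_triangle_mesh):
        with pytest.raises(FieldError):
            residual_contrast(np.array([0.5, 1.5]), two_triangle_mesh)


class TestDyeLocalization:
    def test_distal_dye_near_one(self):
        mesh = _laa_rect_mesh()
        cl = extract_centerline(mesh, 10)
        tip = cl.positions[-1]
        c = np.zeros(mesh.n_cells)
        near_tip = np.linalg.norm(mesh.cell_centroids - tip, axis=1) < 0.15
        c[near_tip] = 1.0
        assert dye_localization(c, cl, mesh) > 0.9

    def test_uniform_dye_symmetric_half(self):
        """Uniform dye along a straight uniform-width LAA localizes at 0.5."""
        mesh = _laa_rect_mesh()
        cl = extract_centerline(mesh, 10)
        c = np.ones(mesh.n_cells)
        assert dye_localization(c, cl, mesh) == pytest.approx(0.5, abs=0.06)

    def test_invariant_under_scaling(self):
        mesh = _laa_rect_mesh()
        cl = extract_centerline(mesh, 10)
        rng = np.random.default_rng(5)
        c = rng.uniform(0.1, 1.0, mesh.n_cells)
        assert dye_localization(0.5 * c, cl, mesh) == pytest.approx(
            dye_localization(c, cl, mesh), rel=1e-12
        )

    def test_zero_dye_raises(self):
        mesh = _laa_rect_mesh()
        cl = extract_centerline(mesh, 10)
        with pytest.raises(FieldError):
            dye_localization(np.zeros(mesh.n_cells), cl, mesh)


class TestCenterlineProfile:
    def test_constant_field(self):
        mesh = _laa_rect_mesh()
        cl = extract_centerline(mesh, 10)
        prof = centerline_profile(np.full(mesh.n_vertices, 3.3), cl, mesh)
        np.testing.assert_allclose(prof, 3.3, rtol=1e-12)

    def test_coordinate_field_recovers_station_x(self):
        mesh = _laa_rect_mesh()
        cl = extract_centerline(mesh, 10)
        prof = centerline_profile(mesh.vertices[:, 0], cl, mesh)
        np.testing.assert_allclose(prof, cl.positions[:, 0], atol=1e-9)

    def test_station_outside_mesh_raises(self):
        mesh = _laa_rect_mesh()
        cl = Centerline(positions=np.array([[-1.0, 0.2], [0.5, 0.2]]),
                        s=np.array([0.0, 1.0]))
        with pytest.raises(InterpolationError):
            centerline_profile(np.zeros(mesh.n_vertices), cl, mesh)


class TestPeriodicityMetric:
    def _snaps(self, scale_b):
        rng = np.random.default_rng(11)
        u = rng.normal(size=50)
        v = rng.normal(size=50)
        snaps = {}
        for ph in range(4):
            snaps[(0, ph)] = (0.1 * ph, u * (ph + 1), v * (ph + 1))
            snaps[(1, ph)] = (0.8 + 0.1 * ph, scale_b * u * (ph + 1), scale_b * v * (ph + 1))
        return snaps

    def test_identical_cycles_zero(self):
        assert periodicity_metric(self._snaps(1.0), 0, 1) == 0.0

    def test_doubled_cycle_is_one(self):
        assert periodicity_metric(self._snaps(2.0), 0, 1) == pytest.approx(1.0)

    def test_mismatched_phases_raise(self):
        snaps = self._snaps(1.0)
        del snaps[(1, 3)]
        with pytest.raises(ValueError):
            periodicity_metric(snaps, 0, 1)
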