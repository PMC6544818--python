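"""Solid angles, sensitive-volume integrals and local-effect-model outputs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import clusterdose as cd
from clusterdose.cell_model import omega_cytoplasm, omega_nucleus, omega_target
from clusterdose.shells import ShellTable


def _mc_solid_angle(r, d, R, n=200_000, seed=0):
    """Monte-Carlo fraction of the sphere of radius r inside the ball."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = np.array([d, 0.0, 0.0]) + r * dirs
    frac = np.mean(np.linalg.norm(pts, axis=1) <= R)
    return 4 * np.pi * frac, frac


class TestSolidAngle:
    def test_full_containment(self):
        assert cd.solid_angle_in_ball(5.0, 0.0, 10.0) == pytest.approx(4 * np.pi)
        assert cd.solid_angle_in_ball(3.0, 2.0, 10.0) == pytest.approx(4 * np.pi)

    def test_disjoint(self):
        assert cd.solid_angle_in_ball(5.0, 100.0, 10.0) == 0.0

    def test_sphere_engulfing_ball(self):
        # the shell at radius r encloses the whole ball: no intersection
        assert cd.solid_angle_in_ball(50.0, 2.0, 10.0) == 0.0

    def test_boundary_centered_half_space(self):
        # centre on the ball boundary: Omega = 2 pi (1 - r/(2R)) -> 2 pi as r -> 0
        R = 10.0
        for r in (0.001, 1.0, 5.0, 19.0):
            expected = 2 * np.pi * (1 - r / (2 * R))
            assert cd.solid_angle_in_ball(r, R, R) == pytest.approx(expected)

    def test_continuity_at_piecewise_boundaries(self):
        d, R = 30.0, 10.0
        for boundary in (R + d, d - R):  # outer and inner contact radii
            lo = cd.solid_angle_in_ball(boundary - 1e-9, d, R)
            hi = cd.solid_angle_in_ball(boundary + 1e-9, d, R)
            assert lo == pytest.approx(hi, abs=1e-6)

    def test_monotone_in_ball_radius(self):
        rs = np.linspace(0.5, 60.0, 40)
        omega_small = cd.solid_angle_in_ball(rs, 20.0, 8.0)
        omega_big = cd.solid_angle_in_ball(rs, 20.0, 15.0)
        assert np.all(omega_big >= omega_small - 1e-12)

    @pytest.mark.parametrize(
        "r,d,R",
        [(5.0, 8.0, 10.0), (12.0, 8.0, 10.0), (3.0, 11.0, 10.0), (25.0, 20.0, 10.0)],
    )
    def test_matches_monte_carlo(self, r, d, R):
        omega = cd.solid_angle_in_ball(r, d, R)
        n = 200_000
        omega_mc, frac = _mc_solid_angle(r, d, R, n=n, seed=17)
        se = 4 * np.pi * np.sqrt(max(frac * (1 - frac), 1e-12) / n)
        assert abs(omega - omega_mc) < 3 * se + 1e-9


class TestTargetSolidAngles:
    geom = cd.CellGeometry(nucleus_radius=7000.0, cell_radius=15000.0,
                           cluster_distance=11000.0, cluster_radius=500.0)

    def test_partition_bounded_by_full_sphere(self):
        rs = np.linspace(100.0, 40000.0, 200)
        total = omega_nucleus(rs, self.geom) + omega_cytoplasm(rs, self.geom)
        assert np.all(total <= 4 * np.pi + 1e-9)
        np.testing.assert_allclose(
            total, cd.solid_angle_in_ball(rs, 11000.0, 15000.0), atol=1e-9
        )

    def test_small_r_in_cytoplasm(self):
        # cluster centre between nucleus and membrane: tiny spheres lie
        # wholly in cytoplasm
        assert omega_cytoplasm(1.0, self.geom) == pytest.approx(4 * np.pi)
        assert omega_nucleus(1.0, self.geom) == 0.0

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            omega_target(100.0, self.geom, "mitochondria")


def _uniform_L_table(r_max=50_000.0, n=2000):
    """S1/S2 for L identically 1, on a uniform radial grid."""
    radii = np.linspace(1.0, r_max, n)
    area = 4 * np.pi * radii**2
    return ShellTable(radii, area, area, np.ones_like(radii))


class TestIntegrals:
    def test_uniform_field_volume_identity(self):
        # L = 1 over a ball of radius R centred on the cluster (d = 0)
        # minus the excluded cluster interior: I1 = (4/3) pi (R^3 - a^3)
        a, R = 500.0, 7000.0
        geom = cd.CellGeometry(nucleus_radius=R, cell_radius=15000.0,
                               cluster_distance=0.0, cluster_radius=a)
        table = _uniform_L_table()
        integ = cd.compute_integrals(table, geom, "nucleus")
        expected = 4 / 3 * np.pi * (R**3 - a**3)
        assert integ.I1 == pytest.approx(expected, rel=1e-4)
        assert integ.I2 == pytest.approx(expected, rel=1e-4)

    def test_include_cluster_interior_switch(self):
        a, R = 500.0, 7000.0
        geom = cd.CellGeometry(nucleus_radius=R, cell_radius=15000.0,
                               cluster_distance=0.0, cluster_radius=a)
        table = _uniform_L_table()
        integ = cd.compute_integrals(table, geom, "nucleus", include_cluster_interior=True)
        assert integ.I1 == pytest.approx(4 / 3 * np.pi * R**3, rel=1e-4)

    def test_central_source_analytic_oracle(self, nobump_params, nobump_kernel,
                                            central_source_cluster, central_activation,
                                            standard_binning, water_transport):
        # single central source, full-space target: I1 equals the closed
        # form 4 pi A lambda e^(-a/lambda) (minus the tail beyond support)
        table = cd.shell_profile(central_activation, central_source_cluster,
                                 nobump_kernel, standard_binning, water_transport,
                                 n_points=64, r_max=42_000.0)
        R_target = 40_000.0
        geom = cd.CellGeometry(nucleus_radius=R_target, cell_radius=41_000.0,
                               cluster_distance=0.0, cluster_radius=500.0)
        integ = cd.compute_integrals(table, geom, "nucleus")
        exact = nobump_params.shell_integral(500.0, R_target)
        assert integ.I1 == pytest.approx(exact, rel=5e-3)

    def test_zero_S2_gives_zero_I2(self):
        radii = np.linspace(1.0, 50_000.0, 500)
        table = ShellTable(radii, 4 * np.pi * radii**2, np.zeros_like(radii),
                           np.ones_like(radii))
        geom = cd.CellGeometry(cluster_distance=7500.0)
        integ = cd.compute_integrals(table, geom, "nucleus")
        assert integ.I2 == 0.0

    def test_insufficient_coverage_names_range(self):
        radii = np.linspace(1.0, 5000.0, 100)
        table = ShellTable(radii, np.ones_like(radii), np.ones_like(radii),
                           np.ones_like(radii))
        geom = cd.CellGeometry(cluster_distance=7500.0)
        with pytest.raises(ValueError, match="missing range"):
            cd.compute_integrals(table, geom, "nucleus")

    def test_target_additivity(self):
        # nucleus-I1 + cytoplasm-I1 = whole-cell-I1 (Omega additivity)
        table = _uniform_L_table()
        geom = cd.CellGeometry(cluster_distance=11000.0)
        i_nuc = cd.compute_integrals(table, geom, "nucleus")
        i_cyt = cd.compute_integrals(table, geom, "cytoplasm")
        i_cell = cd.compute_integrals(table, geom, "cell")
        assert i_nuc.I1 + i_cyt.I1 == pytest.approx(i_cell.I1, rel=1e-9)

    def test_receding_cluster_never_gains_dose(self, nobump_kernel, central_source_cluster,
                                               central_activation, standard_binning,
                                               water_transport):
        table = cd.shell_profile(central_activation, central_source_cluster,
                                 nobump_kernel, standard_binning, water_transport,
                                 n_points=64, r_max=60_000.0)
        last = np.inf
        for d in (16000.0, 20000.0, 26000.0, 35000.0):
            geom = cd.CellGeometry(cluster_distance=d)
            i1 = cd.compute_integrals(table, geom, "cell").I1
            assert i1 <= last + 1e-12
            last = i1


class TestLEM:
    def test_no_enhancement_baseline(self):
        lq = cd.LQParams(0.3, 0.03, 2.0, 1e12)
        n = cd.lethal_lesions(lq, cd.EnhancementIntegrals(0.0, 0.0))
        assert n == pytest.approx(0.3 * 2 + 0.03 * 4)

    def test_linear_limit(self):
        lq = cd.LQParams(0.3, 0.0, 2.0, 10.0)
        n = cd.lethal_lesions(lq, cd.EnhancementIntegrals(2.0, 5.0))
        assert n == pytest.approx(0.3 * 2 * (1 + 2.0 / 10.0))

    def test_hand_evaluated_lesion_count(self):
        # alpha=0.1, beta=0.05, D=1, I1/V=0.2, I2/V=0.01
        lq = cd.LQParams(0.1, 0.05, 1.0, 1.0)
        n = cd.lethal_lesions(lq, cd.EnhancementIntegrals(0.2, 0.01))
        assert n == pytest.approx(0.1905, rel=1e-12)

    def test_def_linear_limit(self):
        lq = cd.LQParams(0.2, 0.0, 1.0, 50.0)
        assert cd.dose_enhancement_factor(lq, 10.0) == pytest.approx(10.0 / 50.0)

    def test_def_zero_I1(self):
        lq = cd.LQParams(0.2, 0.05, 1.0, 50.0)
        assert cd.dose_enhancement_factor(lq, 0.0) == 0.0

    def test_def_undefined_without_lq_response(self):
        lq = cd.LQParams(0.0, 0.0, 1.0, 50.0)
        with pytest.raises(ValueError):
            cd.dose_enhancement_factor(lq, 1.0)

    @given(
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=0.0, max_value=0.2),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=1.0, max_value=1e13),
    )
    def test_def_is_relative_lesion_enhancement(self, alpha, beta, dose, I1, V):
        # DEF == (N(I1, I2=0) - N(0,0)) / N(0,0) exactly
        lq = cd.LQParams(alpha, beta, dose, V)
        base = cd.lethal_lesions(lq, cd.EnhancementIntegrals(0.0, 0.0))
        enh = cd.lethal_lesions(lq, cd.EnhancementIntegrals(I1, 0.0))
        assert cd.dose_enhancement_factor(lq, I1) == pytest.approx(
            (enh - base) / base, rel=1e-9, abs=1e-12
        )
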