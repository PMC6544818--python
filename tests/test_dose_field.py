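"""Chord geometry, effective distance and kernel superposition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import clusterdose as cd
from clusterdose.activation import ActivationSet
from clusterdose.dose_field import effective_distance_line_integral


def _random_source_field(rng, n, cluster_radius=500.0, r_agent=26.0):
    src_dir = rng.normal(size=(n, 3))
    src_dir /= np.linalg.norm(src_dir, axis=1, keepdims=True)
    src = src_dir * (cluster_radius - r_agent) * rng.random((n, 1)) ** (1 / 3)
    fld = rng.uniform(-1500, 1500, size=(n, 3))
    return src, fld


class TestChord:
    def test_center_to_outside_is_radius(self):
        chord = cd.segment_cluster_chord(np.zeros(3), np.array([900.0, 0, 0]), 500.0)
        assert chord == pytest.approx(500.0)

    def test_fully_interior_segment(self):
        a, b = np.array([100.0, 0, 0]), np.array([-50.0, 120.0, 0])
        chord = cd.segment_cluster_chord(a, b, 500.0)
        assert chord == pytest.approx(np.linalg.norm(b - a))

    def test_matches_indicator_quadrature(self):
        rng = np.random.default_rng(9)
        src, fld = _random_source_field(rng, 20)
        ts = np.linspace(0.0, 1.0, 400_001)
        for a, b in zip(src, fld):
            chord = cd.segment_cluster_chord(a, b, 500.0)
            pts = a + ts[:, None] * (b - a)
            inside = np.linalg.norm(pts, axis=1) <= 500.0
            numeric = inside.mean() * np.linalg.norm(b - a)
            assert chord == pytest.approx(numeric, abs=np.linalg.norm(b - a) * 1e-5)

    def test_coincident_points(self):
        p = np.array([10.0, 20.0, 30.0])
        assert cd.segment_cluster_chord(p, p, 500.0) == 0.0


class TestEffectiveDistance:
    def test_identity_when_k_is_one(self):
        rng = np.random.default_rng(10)
        src, fld = _random_source_field(rng, 1000)
        g = cd.effective_distance(src, fld, 500.0, 26.0, 1.0)
        d = np.linalg.norm(fld - src, axis=1)
        np.testing.assert_array_equal(g, d)  # bit-equal: same evaluation path

    def test_central_source_hand_value(self):
        # source at centre, field at 1000 nm, k = 2:
        # g = 26 + 2*(500-26) + 500 = 1474 nm
        g = cd.effective_distance(np.zeros(3), np.array([1000.0, 0, 0]), 500.0, 26.0, 2.0)
        assert g == pytest.approx(1474.0)

    def test_field_on_agent_surface(self):
        g = cd.effective_distance(np.zeros(3), np.array([26.0, 0, 0]), 500.0, 26.0, 3.0)
        assert g == pytest.approx(26.0)

    def test_field_inside_agent_uses_euclidean(self):
        g = cd.effective_distance(np.zeros(3), np.array([5.0, 0, 0]), 500.0, 26.0, 3.0)
        assert g == pytest.approx(5.0)

    @given(st.floats(min_value=1.0, max_value=3.0), st.integers(min_value=0, max_value=2**31 - 1))
    def test_correction_never_shortens(self, k, seed):
        rng = np.random.default_rng(seed)
        src, fld = _random_source_field(rng, 50)
        g = cd.effective_distance(src, fld, 500.0, 26.0, k)
        d = np.linalg.norm(fld - src, axis=1)
        assert np.all(g >= d - 1e-9)


class TestLineIntegralReference:
    def test_uniform_profile_matches_closed_form(self):
        rng = np.random.default_rng(11)
        src, fld = _random_source_field(rng, 10)
        k = 1.7

        def profile(p):
            return k if np.linalg.norm(p) <= 500.0 else 1.0

        for a, b in zip(src, fld):
            if np.linalg.norm(b - a) < 26.0:
                continue
            g_quad = effective_distance_line_integral(a, b, profile, 26.0)
            g_ana = cd.effective_distance(a, b, 500.0, 26.0, k)
            assert g_quad == pytest.approx(g_ana, rel=1e-9)

    def test_unit_profile_gives_euclidean(self):
        a, b = np.array([50.0, 0, 0]), np.array([700.0, 100.0, 0])
        g = effective_distance_line_integral(a, b, lambda p: 1.0, 26.0)
        assert g == pytest.approx(np.linalg.norm(b - a), rel=1e-12)

    def test_piecewise_step_profile(self):
        # ratio 2 for |x| < 250 (about a source at the origin), 1 beyond:
        # radial path to 600 nm gives g = 26 + 2*(250-26) + (600-250)
        a = np.zeros(3)
        b = np.array([600.0, 0.0, 0.0])

        def profile(p):
            return 2.0 if np.linalg.norm(p) < 250.0 else 1.0

        g = effective_distance_line_integral(a, b, profile, 26.0)
        assert g == pytest.approx(26.0 + 2 * (250.0 - 26.0) + 350.0, rel=1e-6)


class TestLocalEnhancement:
    def test_empty_activation_is_zero(self, nobump_kernel, central_source_cluster, water_transport):
        act = ActivationSet(np.empty(0, dtype=int), np.empty(0, dtype=int), 1.0, 0.0)
        L = cd.local_enhancement(act, central_source_cluster, nobump_kernel,
                                 np.array([300.0, 0, 0]), water_transport)
        assert L == 0.0

    def test_single_central_source(self, nobump_kernel, central_source_cluster,
                                   central_activation, water_transport):
        r = 700.0
        L = cd.local_enhancement(central_activation, central_source_cluster,
                                 nobump_kernel, np.array([r, 0, 0]), water_transport)
        assert L == pytest.approx(nobump_kernel.evaluate(r), rel=1e-12)

    def test_superposition_linearity(self, nobump_kernel, water_transport):
        centers = np.array([[100.0, 0, 0], [-150.0, 50.0, 0]])
        cluster = cd.Cluster(centers, 26.0, 500.0)
        p = np.array([800.0, 200.0, -100.0])
        both = ActivationSet(np.array([0, 1]), np.array([2, 3]), 1.0, 0.1)
        first = ActivationSet(np.array([0]), np.array([2]), 1.0, 0.1)
        second = ActivationSet(np.array([1]), np.array([3]), 1.0, 0.1)
        L_both = cd.local_enhancement(both, cluster, nobump_kernel, p, water_transport)
        L_sum = (cd.local_enhancement(first, cluster, nobump_kernel, p, water_transport)
                 + cd.local_enhancement(second, cluster, nobump_kernel, p, water_transport))
        assert L_both == pytest.approx(L_sum, rel=1e-12)

    def test_event_count_scales_dose(self, nobump_kernel, central_source_cluster, water_transport):
        p = np.array([600.0, 0, 0])
        one = ActivationSet(np.array([0]), np.array([1]), 1.0, 0.1)
        five = ActivationSet(np.array([0]), np.array([5]), 1.0, 0.1)
        L1 = cd.local_enhancement(one, central_source_cluster, nobump_kernel, p, water_transport)
        L5 = cd.local_enhancement(five, central_source_cluster, nobump_kernel, p, water_transport)
        assert L5 == pytest.approx(5 * L1, rel=1e-12)

    def test_mixture_correction_never_raises_dose(self, nobump_kernel, packed_cluster):
        rng = np.random.default_rng(12)
        act = cd.sample_activations_poisson(packed_cluster, 10 / 711, 1.0, rng)
        pts = rng.uniform(-1200, 1200, size=(50, 3))
        L_plain = cd.local_enhancement(act, packed_cluster, nobump_kernel, pts,
                                       cd.TransportConfig(1.0, 1.0))
        L_corr = cd.local_enhancement(act, packed_cluster, nobump_kernel, pts,
                                      cd.TransportConfig(1.5, 1.0))
        assert np.all(L_corr <= L_plain + 1e-15)

    def test_vectorized_matches_scalar_loop(self, nobump_kernel, packed_cluster):
        rng = np.random.default_rng(13)
        act = cd.sample_activations_poisson(packed_cluster, 10 / 711, 1.0, rng)
        cfg = cd.TransportConfig(1.3, 1.0)
        pts = rng.uniform(-900, 900, size=(20, 3))
        L_vec = cd.local_enhancement(act, packed_cluster, nobump_kernel, pts, cfg)
        L_scal = [cd.local_enhancement(act, packed_cluster, nobump_kernel, p, cfg) for p in pts]
        np.testing.assert_allclose(L_vec, L_scal, rtol=1e-12)

    def test_out_of_range_index_raises(self, nobump_kernel, central_source_cluster, water_transport):
        act = ActivationSet(np.array([5]), np.array([1]), 1.0, 0.1)
        with pytest.raises(IndexError):
            cd.local_enhancement(act, central_source_cluster, nobump_kernel,
                                 np.array([100.0, 0, 0]), water_transport)
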