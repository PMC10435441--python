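import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sweatsense.mc_transport import (
    PhotonPacket,
    SensorGeometry,
    SimConfig,
    TransportError,
    attenuate_weight,
    fresnel_reflectance,
    henyey_greenstein_pdf,
    run_mc,
    sample_free_path,
    sample_scatter_direction,
    trace_photon,
)
from sweatsense.optics_model import build_skin_stack

from conftest import toy_layer, toy_stack
from _oracles import two_layer_reflectance


class TestFreePath:
    def test_closed_form(self):
        assert sample_free_path(1.0, math.exp(-1.0)) == pytest.approx(1.0)

    def test_mean_within_three_se(self):
        rng = np.random.default_rng(0)
        u = rng.random(100_000)
        draws = -np.log(u) / 2.5  # same closed form, vectorized
        single = sample_free_path(2.5, float(u[0]))
        assert single == pytest.approx(draws[0])
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - 1 / 2.5) < 3 * se

    def test_doubling_mu_halves_mean(self):
        rng = np.random.default_rng(1)
        u = rng.random(20_000)
        m1 = np.mean([-math.log(x) / 1.0 for x in u])
        m2 = np.mean([-math.log(x) / 2.0 for x in u])
        assert m1 / m2 == pytest.approx(2.0)

    def test_exponential_goodness_of_fit(self):
        rng = np.random.default_rng(2)
        draws = np.array([sample_free_path(3.0, u) for u in rng.random(100_000)])
        _, p = stats.kstest(draws, "expon", args=(0, 1 / 3.0))
        assert p > 0.01

    def test_domain_errors(self):
        with pytest.raises(TransportError):
            sample_free_path(0.0, 0.5)
        with pytest.raises(TransportError):
            sample_free_path(-1.0, 0.5)
        with pytest.raises(TransportError):
            sample_free_path(1.0, 0.0)


class TestScatterDirection:
    def test_isotropic_pdf_value(self):
        # phase function at g=0 is 1/(4*pi) for every angle
        vals = henyey_greenstein_pdf(np.linspace(-1, 1, 11), 0.0)
        np.testing.assert_allclose(vals, 1.0 / (4 * math.pi))

    def test_pdf_normalizes_to_one(self):
        # numerical integral over the sphere: 2*pi * int p(ct) dct = 1
        for g in (0.0, 0.5, 0.9):
            ct = np.linspace(-1, 1, 200_001)
            integral = 2 * math.pi * np.trapezoid(henyey_greenstein_pdf(ct, g), ct)
            assert integral == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_mean_cosine_equals_g(self, g):
        rng = np.random.default_rng(3)
        incoming = np.array([0.0, 0.0, 1.0])
        n = 100_000
        cos = np.empty(n)
        for i in range(n):
            new = sample_scatter_direction(g, incoming, rng.random(), rng.random())
            cos[i] = new @ incoming
        se = cos.std(ddof=1) / math.sqrt(n)
        assert abs(cos.mean() - g) < 3 * se

    def test_deflection_goodness_of_fit(self):
        g = 0.7
        rng = np.random.default_rng(4)
        incoming = np.array([0.0, 0.0, 1.0])
        cos = np.array(
            [
                sample_scatter_direction(g, incoming, rng.random(), rng.random())[2]
                for _ in range(100_000)
            ]
        )

        def cdf(ct):
            return ((1 - g * g) / (2 * g)) * (
                1.0 / np.sqrt(1 + g * g - 2 * g * ct) - 1.0 / (1 + g)
            )

        _, p = stats.kstest(cos, cdf)
        assert p > 0.01

    def test_output_is_unit_vector(self):
        rng = np.random.default_rng(5)
        d = np.array([0.6, 0.0, 0.8])
        for _ in range(100):
            new = sample_scatter_direction(0.85, d, rng.random(), rng.random())
            assert np.linalg.norm(new) == pytest.approx(1.0, abs=1e-9)
            d = new

    def test_invalid_g_rejected(self):
        with pytest.raises(TransportError):
            sample_scatter_direction(1.0, np.array([0, 0, 1.0]), 0.5, 0.5)


class TestAttenuateWeight:
    def test_closed_form(self):
        w, absorbed = attenuate_weight(1.0, 0.5, 2.0)
        assert w == pytest.approx(math.exp(-1.0))
        assert absorbed == pytest.approx(1.0 - math.exp(-1.0))

    def test_zero_mu_a_is_identity(self):
        w, absorbed = attenuate_weight(0.7, 0.0, 5.0)
        assert w == 0.7
        assert absorbed == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        w=st.floats(1e-6, 1.0),
        mua=st.floats(0.0, 10.0),
        l1=st.floats(0.0, 5.0),
        l2=st.floats(0.0, 5.0),
    )
    def test_segment_composition_property(self, w, mua, l1, l2):
        w12, _ = attenuate_weight(w, mua, l1 + l2)
        w1, _ = attenuate_weight(w, mua, l1)
        if w1 > 0:
            w2, _ = attenuate_weight(w1, mua, l2)
            assert w12 == pytest.approx(w2, rel=1e-12)


class TestFresnel:
    def test_normal_incidence(self):
        assert fresnel_reflectance(1.0, 1.5, 1.0) == pytest.approx(0.04)

    def test_matched_boundary(self):
        assert fresnel_reflectance(1.4, 1.4, 0.31) == 0.0

    def test_total_internal_reflection(self):
        critical = math.asin(1.0 / 1.4)  # ~45.6 degrees
        cos_beyond = math.cos(critical + 0.05)
        assert fresnel_reflectance(1.4, 1.0, cos_beyond) == 1.0


class TestTracePhoton:
    def test_beer_lambert_limit(self):
        # purely absorbing slab, matched boundaries, normal incidence
        stack = toy_stack([toy_layer(2.0, 0.7, 0.0)])
        geo = SensorGeometry.full_surface()
        cfg = SimConfig(photons=1, seed=0)
        event, w, absorbed = trace_photon(stack, geo, cfg, 970.0)
        assert event == "transmitted"
        assert w == pytest.approx(math.exp(-0.7 * 2.0))
        assert w + absorbed == pytest.approx(1.0)

    def test_determinism(self):
        stack = toy_stack([toy_layer(math.inf, 0.3, 3.0, g=0.8, n=1.4)])
        geo = SensorGeometry.full_surface()
        cfg = SimConfig(photons=1, seed=42)
        r1 = trace_photon(stack, geo, cfg, 970.0)
        r2 = trace_photon(stack, geo, cfg, 970.0)
        assert r1 == r2


class TestRunMc:
    def test_beer_lambert_transmission(self):
        stack = toy_stack([toy_layer(2.0, 0.7, 0.0)])
        rec = run_mc(stack, SensorGeometry.full_surface(), SimConfig(photons=2000), 970.0)
        t = rec.transmitted_weight / rec.launched_weight
        assert t == pytest.approx(math.exp(-1.4), rel=1e-9)

    def test_non_absorbing_conservation(self):
        stack = toy_stack([toy_layer(1.0, 0.0, 5.0, g=0.5)])
        rec = run_mc(stack, SensorGeometry.full_surface(), SimConfig(photons=5000), 970.0)
        total = rec.detected_weight + rec.escaped_weight + rec.transmitted_weight
        assert total == pytest.approx(rec.launched_weight, rel=1e-9)
        assert rec.absorbed_weight == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("film_mm", [0.0, 0.2])
    def test_weight_conservation_skin_stack(self, nir_grid, film_mm):
        stack = build_skin_stack(grid=nir_grid, film_thickness_mm=film_mm)
        for wl in (970.0, 1450.0):
            rec = run_mc(
                stack,
                SensorGeometry(),
                SimConfig(photons=20_000, seed=11),
                wl,
            )
            assert rec.conservation_residual() < 1e-6
            assert rec.truncated_count < 0.001 * rec.photons
            assert 0.0 <= rec.reflectance <= 1.0

    def test_determinism_contract(self, default_stack):
        cfg = SimConfig(photons=3000, seed=7)
        r1 = run_mc(default_stack, SensorGeometry(), cfg, 1450.0)
        r2 = run_mc(default_stack, SensorGeometry(), cfg, 1450.0)
        assert r1.detected_weight == r2.detected_weight
        assert r1.absorbed_weight == r2.absorbed_weight
        assert r1.escaped_weight == r2.escaped_weight

    def test_zero_thickness_film_equals_no_film(self, nir_grid):
        bare = build_skin_stack(grid=nir_grid)
        thin = build_skin_stack(grid=nir_grid, film_thickness_mm=1e-7)
        geo = SensorGeometry.full_surface()
        ra = run_mc(bare, geo, SimConfig(photons=20_000, seed=3), 1450.0)
        rb = run_mc(thin, geo, SimConfig(photons=20_000, seed=3), 1450.0)
        se = math.hypot(ra.standard_error, rb.standard_error)
        # film layer introduces an n=1.33 interface; allow its tiny specular
        # offset plus MC error
        assert abs(ra.reflectance - rb.reflectance) < 0.02 + 3 * se

    def test_reflectance_monotone_in_absorption(self):
        geo = SensorGeometry.full_surface()
        refl = []
        ses = []
        for mua in (0.1, 0.5, 2.0):
            stack = toy_stack([toy_layer(math.inf, mua, 5.0, g=0.7)])
            rec = run_mc(stack, geo, SimConfig(photons=30_000, seed=9), 970.0)
            refl.append(rec.total_top_exit)
            ses.append(math.sqrt(rec.reflectance * (1 - rec.reflectance) / rec.photons))
        assert refl[0] - refl[1] > 3 * math.hypot(ses[0], ses[1])
        assert refl[1] - refl[2] > 3 * math.hypot(ses[1], ses[2])

    def test_two_layer_oracle_equivalence(self):
        d1, mua1, mus1, g1 = 1.0, 0.1, 2.0, 0.5
        mua2, mus2, g2 = 0.5, 1.0, 0.0
        stack = toy_stack(
            [
                toy_layer(d1, mua1, mus1, g=g1),
                toy_layer(math.inf, mua2, mus2, g=g2),
            ]
        )
        rec = run_mc(
            stack, SensorGeometry.full_surface(), SimConfig(photons=50_000, seed=21), 970.0
        )
        r_impl = rec.total_top_exit
        se_impl = math.sqrt(r_impl * (1 - r_impl) / rec.photons)
        r_oracle, se_oracle = two_layer_reflectance(
            d1, mua1, mus1, g1, mua2, mus2, g2, n_photons=50_000, seed=77
        )
        assert abs(r_impl - r_oracle) < 3 * math.hypot(se_impl, se_oracle)


class TestTypesValidation:
    def test_photon_packet_invariants(self):
        with pytest.raises(TransportError):
            PhotonPacket(np.zeros(3), np.array([0.0, 0.0, 2.0]), 0.5, 0)
        with pytest.raises(TransportError):
            PhotonPacket(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0, 0)
        p = PhotonPacket(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0, 0)
        assert p.weight == 1.0

    def test_sensor_geometry_invariants(self):
        with pytest.raises(TransportError):
            SensorGeometry(detector_side_mm=0.0)
        with pytest.raises(TransportError):
            SensorGeometry(incidence_deg=90.0)

    def test_sim_config_invariants(self):
        with pytest.raises(TransportError):
            SimConfig(photons=0)
        with pytest.raises(TransportError):
            SimConfig(roulette_threshold=1.5)
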