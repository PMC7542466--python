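"""MP unit conversions, aggregation kinetics, grazing uptake, tendencies."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpsink.ecosystem import (EcoFluxes, EcoParams, EcoState, max_growth,
                              renormalise_preferences, PreferenceSet)
from mpsink.microplastic import (MPState, aggregate_count, aggregate_release,
                                 aggregation_uptake, mass_to_particles,
                                 mp_as_nitrogen, mp_grazing, mp_tendencies,
                                 particles_to_mass, pellet_release)
from mpsink.params import MPParameters, fixture


class TestMassConversion:
    def test_reference_conversion(self):
        assert mass_to_particles(236.0e3) == pytest.approx(51.2e12)

    def test_zero(self):
        assert mass_to_particles(0.0) == 0.0

    def test_single_particle_mass_grams(self):
        grams = particles_to_mass(1.0) * 1.0e6  # tonnes -> g
        assert grams == pytest.approx(4.609375e-3, rel=1e-6)

    @given(st.floats(0.0, 1e12))
    def test_round_trip(self, mass):
        assert particles_to_mass(mass_to_particles(mass)) == pytest.approx(
            mass, rel=1e-12, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mass_to_particles(-1.0)


class TestAggregateCount:
    def test_zero(self):
        assert aggregate_count(0.0) == 0.0

    def test_unit_detritus_source(self):
        # 1 mmol N -> 6.625 mmol C -> 6.625 * 12011 ug C / 8.8 ug per aggregate
        assert aggregate_count(1.0) == pytest.approx(9.042e3, rel=1e-3)

    def test_linearity(self):
        x = 0.37
        assert aggregate_count(2 * x) == pytest.approx(2 * aggregate_count(x))


class TestAggregationUptake:
    def test_half_saturation(self):
        full = aggregation_uptake(1e12, 1.0, k_P=5.0, F_A=0.4)
        half = aggregation_uptake(5.0, 1.0, k_P=5.0, F_A=0.4)
        assert half == pytest.approx(full / 2.0, rel=1e-6)

    def test_zero_mp(self):
        assert aggregation_uptake(0.0, 1.0, k_P=5.0, F_A=0.5) == 0.0

    def test_degenerate_zero_k_and_mp(self):
        assert aggregation_uptake(0.0, 1.0, k_P=0.0, F_A=0.5) == 0.0

    def test_test_lo_worked_example(self):
        out = aggregation_uptake(1.0, 1.0, k_P=0.424, F_A=0.003)
        assert out == pytest.approx((1 / 1.424) * 9042 * 0.003, rel=1e-3)

    @given(st.floats(0.0, 1e4))
    def test_bounded_by_saturated_uptake(self, mp):
        out = aggregation_uptake(mp, 2.0, k_P=10.0, F_A=0.3)
        assert out <= aggregate_count(2.0) * 0.3 + 1e-9


class TestRelease:
    def test_zero_pools(self):
        assert aggregate_release(0.0, 0.3) == 0.0
        assert pellet_release(0.0, 0.3) == 0.0

    def test_linear_products(self):
        assert aggregate_release(50.0, 0.1) == pytest.approx(5.0)
        assert pellet_release(10.0, 0.2) == pytest.approx(2.0)

    def test_same_rate_constant_for_both_pools(self):
        assert aggregate_release(7.0, 0.13) == pellet_release(7.0, 0.13)

    def test_warmer_layer_releases_more(self):
        from mpsink.ecosystem import remin_rate
        p = EcoParams()
        assert aggregate_release(5.0, remin_rate(28.0, p)) > aggregate_release(
            5.0, remin_rate(5.0, p))


class TestMPGrazing:
    def _eco(self, **kw):
        s = EcoState.zeros(1)
        for k, v in kw.items():
            setattr(s, k, np.full(1, float(v)))
        return s

    def test_zero_preference(self):
        params = fixture("test_med").with_values(psi_MP=0.0)
        out = mp_grazing(np.array([10.0]), self._eco(Z=1.0, PH=0.5),
                         renormalise_preferences(0.0), 20.0, params, EcoParams())
        assert np.all(out == 0.0)

    def test_zero_zooplankton(self):
        params = fixture("test_med")
        out = mp_grazing(np.array([10.0]), self._eco(PH=0.5),
                         renormalise_preferences(params.psi_MP), 20.0,
                         params, EcoParams())
        assert np.all(out == 0.0)

    def test_single_prey_half_saturation(self):
        """With MP as the only prey at k_Z (in N units), G = mu_max * Z / 2."""
        eco_p = EcoParams()
        params = MPParameters(psi_MP=0.9, F_T=0.1)
        conv = params.mp_particle_to_mmol_n
        mp_free = eco_p.k_Z / 0.9 / conv  # psi_MP * mp_as_N == k_Z
        prefs = PreferenceSet(psi_CO=0, psi_PH=0, psi_DZ=0.1, psi_Detr=0,
                              psi_Z=0, psi_MP=0.9)
        out = mp_grazing(np.array([mp_free]), self._eco(Z=0.5), prefs, 15.0,
                         params, eco_p)
        g_expected = max_growth(15.0, eco_p) * 0.5 / 2.0
        assert out[0] == pytest.approx(g_expected / conv)


class TestTendencies:
    def _setup(self, n=3, det_source=0.0, mu_d=0.0):
        eco = EcoState.zeros(n)
        fluxes = EcoFluxes(det_a_source=np.full(n, det_source),
                           pellet_production=np.zeros(n),
                           mu_D=np.full(n, mu_d), npp=np.zeros(n),
                           grazing_food=np.zeros(n), grazing_mp_n=np.zeros(n))
        return eco, fluxes

    def test_no_biology_no_emission_inert(self):
        eco, fluxes = self._setup()
        mp = MPState.zeros(3)
        t = mp_tendencies(mp, eco, fluxes, renormalise_preferences(0.0),
                          np.full(3, 20.0), fixture("test_med"), EcoParams(),
                          emission=0.0)
        for arr in (t.d_free, t.d_A, t.d_Z):
            np.testing.assert_allclose(arr, 0.0)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 50.0), st.floats(0.0, 50.0),
           st.floats(0.0, 10.0))
    def test_local_conservation_identity(self, free, a, z, emis):
        """d(MP_free) + d(MP_A) + d(MP_Z) equals the emission, any state."""
        eco = EcoState.zeros(2)
        eco.Z = np.array([0.3, 0.1])
        eco.PH = np.array([0.4, 0.2])
        fluxes = EcoFluxes(det_a_source=np.array([0.01, 0.002]),
                           pellet_production=np.zeros(2),
                           mu_D=np.array([0.2, 0.1]), npp=np.zeros(2),
                           grazing_food=np.zeros(2), grazing_mp_n=np.zeros(2))
        mp = MPState(np.full(2, free), np.full(2, a), np.full(2, z))
        params = fixture("test_med")
        emission = np.array([emis, 0.0])
        t = mp_tendencies(mp, eco, fluxes, renormalise_preferences(params.psi_MP),
                          np.full(2, 25.0), params, EcoParams(), emission, dt=0.5)
        np.testing.assert_allclose(t.d_free + t.d_A + t.d_Z, emission,
                                   rtol=1e-10, atol=1e-12)

    def test_passive_tracer_limit(self):
        """F_A = 0 and psi_MP = 0: emission is the only tendency."""
        eco = EcoState.zeros(2)
        eco.Z = np.array([0.5, 0.5])
        fluxes = EcoFluxes(det_a_source=np.full(2, 0.1),
                           pellet_production=np.zeros(2),
                           mu_D=np.full(2, 0.3), npp=np.zeros(2),
                           grazing_food=np.zeros(2), grazing_mp_n=np.zeros(2))
        mp = MPState(np.array([5.0, 2.0]), np.zeros(2), np.zeros(2))
        params = MPParameters(F_T=0.3, F_A=0.0, psi_MP=0.0)
        emission = np.array([1.5, 0.0])
        t = mp_tendencies(mp, eco, fluxes, renormalise_preferences(0.0),
                          np.full(2, 25.0), params, EcoParams(), emission)
        np.testing.assert_allclose(t.d_free, emission)
        np.testing.assert_allclose(t.d_A, 0.0)
        np.testing.assert_allclose(t.d_Z, 0.0)

    def test_uptake_limited_by_available_mp(self):
        eco = EcoState.zeros(1)
        eco.Z = np.array([5.0])
        fluxes = EcoFluxes(det_a_source=np.array([10.0]),
                           pellet_production=np.zeros(1),
                           mu_D=np.zeros(1), npp=np.zeros(1),
                           grazing_food=np.zeros(1), grazing_mp_n=np.zeros(1))
        mp = MPState(np.array([1.0]), np.zeros(1), np.zeros(1))
        params = fixture("test_lo")  # tiny k_P: near-saturated uptake
        dt = 1.0
        t = mp_tendencies(mp, eco, fluxes, renormalise_preferences(params.psi_MP),
                          np.full(1, 28.0), params, EcoParams(), 0.0, dt=dt)
        assert (t.A_upt[0] + t.P_upt[0]) * dt <= mp.MP_free[0] + 1e-12

    def test_mp_as_nitrogen_conversion(self):
        params = MPParameters(R_F_MP=1.0)
        # one particle/m3 -> grams -> mol N -> mmol N
        expected = params.grams_per_particle * params.r_n_f * 1e3
        assert mp_as_nitrogen(1.0, params) == pytest.approx(expected)
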