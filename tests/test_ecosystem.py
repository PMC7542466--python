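"""NPZD ecosystem: preferences, temperature laws, grazing, conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpsink.ecosystem import (EcoParams, EcoState, PreferenceSet, grazing_rates,
                              max_growth, remin_rate, renormalise_preferences,
                              step_ecosystem)


@pytest.fixture
def params():
    return EcoParams()


class TestPreferences:
    def test_no_mp_split(self):
        p = renormalise_preferences(0.0)
        assert p.psi_DZ == 0.1
        for v in (p.psi_CO, p.psi_PH, p.psi_Detr, p.psi_Z):
            assert v == pytest.approx(0.225)

    def test_test_med_split(self):
        p = renormalise_preferences(0.193)
        assert p.psi_CO == pytest.approx((1 - 0.1 - 0.193) / 4) == pytest.approx(0.17675)

    def test_boundary_all_to_mp(self):
        p = renormalise_preferences(0.9)
        assert p.psi_CO == pytest.approx(0.0)
        assert p.psi_DZ == 0.1

    def test_overfull_rejected(self):
        with pytest.raises(ValueError):
            renormalise_preferences(0.95)

    @given(st.floats(0.0, 0.9))
    def test_sum_is_one(self, psi_mp):
        p = renormalise_preferences(psi_mp)
        total = (p.psi_CO + p.psi_PH + p.psi_DZ + p.psi_Detr + p.psi_Z + p.psi_MP)
        assert total == pytest.approx(1.0)

    def test_invalid_sum_rejected(self):
        with pytest.raises(ValueError):
            PreferenceSet(psi_CO=0.5, psi_PH=0.5, psi_DZ=0.5, psi_Detr=0.0,
                          psi_Z=0.0, psi_MP=0.0)


class TestTemperatureLaws:
    def test_remin_reference(self, params):
        assert remin_rate(0.0, params) == pytest.approx(params.mu_D0)

    def test_remin_q10_doubling(self):
        p = EcoParams(q10_remin=2.0)
        assert remin_rate(10.0, p) == pytest.approx(2.0 * p.mu_D0)

    def test_remin_warm_exceeds_cold(self, params):
        assert remin_rate(28.0, params) > remin_rate(5.0, params)

    def test_growth_capped_above_20(self, params):
        assert max_growth(25.0, params) == pytest.approx(max_growth(20.0, params))

    def test_growth_monotone_below_cap(self, params):
        assert max_growth(10.0, params) < max_growth(20.0, params)

    @pytest.mark.parametrize("eps", [0.1, 5.0, 15.0])
    def test_growth_plateau(self, params, eps):
        assert max_growth(20.0 + eps, params) == max_growth(20.0, params)


def _state(**kw):
    n = 1
    s = EcoState.zeros(n)
    for k, v in kw.items():
        setattr(s, k, np.full(n, float(v)))
    return s


class TestGrazing:
    def test_no_prey_no_grazing(self, params):
        s = _state(Z=1.0)
        g = grazing_rates(s, renormalise_preferences(0.2), 20.0, params)
        for k in ("CO", "PH", "DZ", "Detr"):
            assert g[k][0] == 0.0

    def test_half_saturation_single_prey(self, params):
        s = _state(PH=params.k_Z, Z=0.5)
        prefs = PreferenceSet(psi_CO=0, psi_PH=1.0, psi_DZ=0, psi_Detr=0,
                              psi_Z=0, psi_MP=0)
        g = grazing_rates(s, prefs, 15.0, params)
        expected = max_growth(15.0, params) * 0.5 / 2.0
        assert g["PH"][0] == pytest.approx(expected)

    def test_mp_presence_reduces_food_grazing(self, params):
        s = _state(PH=0.3, CO=0.2, DZ=0.1, Z=0.4, DET_A=0.1, DET_Z=0.1)
        g_without = grazing_rates(s, renormalise_preferences(0.0), 22.0, params)
        g_with = grazing_rates(s, renormalise_preferences(0.2), 22.0, params,
                               mp_as_N=0.3)
        for prey in ("PH", "CO", "Detr", "Z"):
            assert g_with[prey][0] < g_without[prey][0]

    def test_total_grazing_bounded(self, params):
        s = _state(PH=50.0, CO=50.0, DZ=50.0, Z=2.0, DET_A=50.0, DET_Z=50.0)
        g = grazing_rates(s, renormalise_preferences(0.1), 30.0, params)
        total = sum(g[k][0] for k in g)
        assert total <= max_growth(30.0, params) * 2.0 + 1e-12


class TestStepEcosystem:
    def test_zero_biology_is_inert(self, params):
        s = EcoState.zeros(3)
        s.N = np.array([1.0, 5.0, 10.0])
        new, fx = step_ecosystem(s, np.full(3, 15.0), np.ones(3), 0.5, params,
                                 renormalise_preferences(0.0))
        np.testing.assert_allclose(new.N, s.N)
        np.testing.assert_allclose(fx.det_a_source, 0.0)
        np.testing.assert_allclose(fx.npp, 0.0)

    def test_nitrogen_conserved_per_step(self, params):
        rng = np.random.default_rng(1)
        s = EcoState(*[rng.random(4) for _ in range(7)])
        thick = np.ones(4)
        before = s.total_nitrogen(thick)
        prefs = renormalise_preferences(0.1)
        for _ in range(200):
            s, fx = step_ecosystem(s, np.full(4, 18.0), np.full(4, 0.4), 0.5,
                                   params, prefs, mp_as_N=0.05)
        after = s.total_nitrogen(thick)
        assert after == pytest.approx(before, rel=1e-10)

    def test_pellet_fraction_splits_particulate_losses(self, params):
        s = _state(PH=0.0, Z=0.5, DET_A=0.0)
        prefs = renormalise_preferences(0.0)
        _, fx = step_ecosystem(s, 20.0 * np.ones(1), np.ones(1), 0.1, params, prefs)
        # no phytoplankton: all marine-snow production is the zooplankton share
        assert fx.pellet_production[0] == pytest.approx(fx.det_a_source[0])

    def test_detritus_sum_independent_of_split(self, params):
        """DET_A + DET_Z evolves as one pool when both share the sinking law."""
        prefs = renormalise_preferences(0.15)
        base = dict(N=0.5, PH=0.3, CO=0.2, DZ=0.1, Z=0.4)
        s1 = _state(**base, DET_A=0.30, DET_Z=0.10)
        s2 = _state(**base, DET_A=0.05, DET_Z=0.35)
        n1, f1 = step_ecosystem(s1, 18.0 * np.ones(1), np.ones(1), 0.5, params, prefs)
        n2, f2 = step_ecosystem(s2, 18.0 * np.ones(1), np.ones(1), 0.5, params, prefs)
        assert (n1.DET_A + n1.DET_Z)[0] == pytest.approx((n2.DET_A + n2.DET_Z)[0])
        np.testing.assert_allclose(n1.Z, n2.Z)
        np.testing.assert_allclose(n1.N, n2.N)
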