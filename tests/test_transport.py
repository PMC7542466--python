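"""Vertical transport: upwind fluxes, rise, seafloor boundary, stepping."""

import numpy as np
import pytest

from mpsink import RunConfig, build_grid, default_grid
from mpsink.forcing import TemperatureScenario, temperature_profile
from mpsink.params import MPParameters, fixture
from mpsink.transport import (SeafloorLedger, Simulation, TransportConfig,
                              apply_diffusion, apply_rise, apply_sinking,
                              rise_flux, seafloor_exchange, sinking_flux)


@pytest.fixture
def grid3():
    return build_grid([50.0, 80.0, 200.0])


class TestSinking:
    def test_zero_concentration_zero_flux(self, grid3):
        np.testing.assert_allclose(
            sinking_flux(np.zeros(3), 10.0, grid3), 0.0)

    def test_uniform_flux(self, grid3):
        flux = sinking_flux(np.full(3, 2.0), 5.0, grid3)
        np.testing.assert_allclose(flux, 10.0)

    def test_depth_dependent_speed(self, grid3):
        w = np.array([5.0, 10.0, 20.0])
        flux = sinking_flux(np.ones(3), w, grid3)
        np.testing.assert_allclose(flux, w)

    def test_cfl_violation_names_layer(self, grid3):
        with pytest.raises(ValueError, match="layer 0"):
            sinking_flux(np.ones(3), 200.0, grid3, dt=1.0)

    def test_apply_sinking_conserves(self, grid3):
        conc = np.array([4.0, 1.0, 0.5])
        before = grid3.column_integral(conc)
        new, bottom = apply_sinking(conc, 10.0, grid3, 0.5)
        assert grid3.column_integral(new) + bottom == pytest.approx(before)

    def test_upwind_no_new_extrema(self, grid3):
        conc = np.array([1.0, 3.0, 2.0])
        new, _ = apply_sinking(conc, 5.0, grid3, 0.5)
        assert new.max() <= conc.max() + 1e-12
        assert new.min() >= 0.0


class TestRise:
    def test_no_rising_fraction(self, grid3):
        np.testing.assert_allclose(rise_flux(np.ones(3), 0.0, 1000.0, grid3), 0.0)

    def test_interface_flux_formula(self, grid3):
        mp = np.array([1.0, 2.0, 3.0])
        w_p = 0.019 * 86400.0
        flux = rise_flux(mp, 0.074, w_p, grid3)
        assert flux[0] == 0.0  # nothing leaves through the sea surface
        assert flux[1] == pytest.approx(0.074 * w_p * 2.0)
        assert flux[2] == pytest.approx(0.074 * w_p * 3.0)

    def test_surface_layer_only_gains(self, grid3):
        mp = np.array([1.0, 5.0, 5.0])
        new = apply_rise(mp, 0.05, 0.019 * 86400.0, grid3, 0.5)
        assert new[0] >= mp[0]

    def test_rise_conserves_particles(self, grid3):
        mp = np.array([1.0, 5.0, 5.0])
        new = apply_rise(mp, 0.08, 0.019 * 86400.0, grid3, 0.5)
        assert grid3.column_integral(new) == pytest.approx(
            grid3.column_integral(mp), rel=1e-12)


class TestDiffusion:
    def test_conserves_and_smooths(self, grid3):
        conc = np.array([10.0, 0.0, 0.0])
        cfg = TransportConfig()
        new = apply_diffusion(conc, grid3, cfg, 0.5)
        assert grid3.column_integral(new) == pytest.approx(
            grid3.column_integral(conc))
        assert new[0] < conc[0] and new[1] > 0.0


class TestSeafloor:
    def test_full_return(self):
        led = SeafloorLedger()
        returned = seafloor_exchange(100.0, 50.0, 1.0, led)
        assert returned == pytest.approx(150.0)
        assert led.lost_total == 0.0

    def test_full_burial(self):
        led = SeafloorLedger()
        returned = seafloor_exchange(100.0, 50.0, 0.0, led)
        assert returned == 0.0
        assert led.lost_total == pytest.approx(150.0)

    def test_test_hi_split(self):
        led = SeafloorLedger()
        returned = seafloor_exchange(100.0, 0.0, 0.888, led)
        assert returned == pytest.approx(88.8)
        assert led.lost_MP_A == pytest.approx(11.2)


def _mini_sim(params, surface_C=28.0, **kw):
    cfg = RunConfig(params=params, fixture_name=None, surface_C=surface_C, **kw)
    return cfg.build_simulation()


class TestSimulation:
    def test_cfl_checked_at_init(self):
        grid = build_grid([5.0, 5.0])
        params = fixture("test_med")
        scen = TemperatureScenario(base_profile=np.array([20.0, 10.0]))
        with pytest.raises(ValueError, match="CFL"):
            Simulation(grid, params, scen, transport=TransportConfig(dt=1.0))

    def test_zero_forcing_stays_empty(self):
        params = fixture("test_med").with_values(F_T=0.0)
        sim = _mini_sim(params, end_year=1952, spinup_years=2)
        out = sim.run(1950, 1952, spinup_years=2)
        assert out.scalars["inventory_total"].max() == 0.0

    def test_pure_physics_mp_stays_at_surface(self):
        """No aggregation, no grazing, no rise, no mixing: the free tracer
        has no vertical pathway and stays in the surface layer."""
        params = MPParameters(F_T=0.2, F_R=0.0, F_A=0.0, psi_MP=0.0)
        cfg = RunConfig(params=params, fixture_name=None, end_year=1953,
                        spinup_years=0,
                        transport_overrides=(("kappa_v", 0.0),
                                             ("kappa_surface", 0.0)))
        sim = cfg.build_simulation()
        sim.eco_on = False
        res = sim.run(1950, 1953, spinup_years=0)
        prof = res.profiles["MP_free"][-1]
        assert prof[0] > 0.0
        np.testing.assert_allclose(prof[1:], 0.0)

    def test_no_biology_equivalence(self):
        """psi_MP = 0 and F_A = 0 reproduces the ecosystem-off MP trajectory."""
        params = fixture("test_hi").with_values(F_A=0.0, psi_MP=0.0)
        a = _mini_sim(params, end_year=1954, spinup_years=2)
        b = _mini_sim(params, end_year=1954, spinup_years=2)
        b.eco_on = False
        ra = a.run(1950, 1954, spinup_years=2)
        rb = b.run(1950, 1954, spinup_years=2)
        np.testing.assert_array_equal(ra.profiles["MP_free"], rb.profiles["MP_free"])
        assert ra.profiles["MP_A"].max() == 0.0

    def test_self_convergence_in_dt(self):
        """Halving dt changes the final inventory by well under 1 %."""
        invs = {}
        for dt in (0.5, 0.25):
            cfg = RunConfig(end_year=1956, spinup_years=3, dt_days=dt)
            res = cfg.build_simulation().run(1950, 1956, spinup_years=3)
            invs[dt] = res.scalars["inventory_total"].iloc[-1]
        assert invs[0.25] == pytest.approx(invs[0.5], rel=1e-2)

    def test_budget_closure_short_run(self, short_run):
        assert abs(short_run.budget_error()) < 1e-9
        assert short_run.stable
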