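"""Vertical transport, seafloor exchange, and the simulation time loop.

Transport is flux-form first-order upwind on the column grid: detritus and
the bound MP pools sink with a speed that increases linearly with depth,
a fraction F_R of free MP below the surface layer rises fast (sub-cycled
internally to respect its much stricter CFL limit), and all tracers mix
vertically with a constant diffusivity (enhanced in the near-surface
layers). Bound MP reaching the seafloor is split by F_B into a part
returned to the bottom-layer free pool (released from its organic matrix)
and a permanent sedimentary loss; sinking detritus reaching the seafloor
is remineralised into bottom-layer nutrient so the closed column conserves
nitrogen exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import forcing as forcing_mod
from .ecosystem import (EcoParams, EcoState, PreferenceSet,
                        renormalise_preferences, step_ecosystem)
from .grid import ColumnGrid, default_grid
from .microplastic import MPState, mp_tendencies
from .params import MPParameters, PARTICLES_PER_TONNE

__all__ = [
    "TransportConfig",
    "SeafloorLedger",
    "sinking_speed",
    "sinking_flux",
    "rise_flux",
    "seafloor_exchange",
    "Simulation",
    "RunResult",
    "run_simulation",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class TransportConfig:
    """Vertical transport parameters (speeds m/d, diffusivities m2/d)."""

    w_D0: float = 14.0          # detrital sinking speed at the surface
    m_w: float = 0.04           # linear depth increase of sinking (d^-1)
    kappa_v: float = 17.0       # interior vertical diffusivity (~2e-4 m2/s)
    kappa_surface: float = 35.0  # enhanced mixed-layer diffusivity
    surface_mix_depth: float = 100.0
    dt: float = 0.5             # time step (days)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kappa_v < 0 or self.kappa_surface < 0:
            raise ValueError("diffusivities must be non-negative")


@dataclass
class SeafloorLedger:
    """Cumulative particles lost to the sediment and returned (per m2)."""

    lost_MP_A: float = 0.0
    lost_MP_Z: float = 0.0
    returned: float = 0.0

    @property
    def lost_total(self) -> float:
        return self.lost_MP_A + self.lost_MP_Z


def sinking_speed(grid: ColumnGrid, cfg: TransportConfig) -> np.ndarray:
    """Per-layer detrital sinking speed w_D(z) = w_D0 + m_w * z (m/d)."""
    return cfg.w_D0 + cfg.m_w * grid.layer_center


def sinking_flux(conc, w, grid: ColumnGrid, dt: float | None = None) -> np.ndarray:
    """Upwind sinking flux through the bottom interface of each layer.

    flux[i] = w[i] * conc[i] (units m^-2 d^-1); the surface has no
    incoming flux. When ``dt`` is given the CFL condition w*dt <= dz is
    checked and a violation names the offending layer.
    """
    conc = np.asarray(conc, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), conc.shape)
    if np.any(w < 0):
        raise ValueError("sinking speeds must be non-negative")
    if dt is not None:
        bad = np.nonzero(w * dt > grid.layer_thickness)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"CFL violation in layer {i}: w*dt = {w[i] * dt:.1f} m exceeds "
                f"thickness {grid.layer_thickness[i]:.1f} m"
            )
    return w * conc


def apply_sinking(conc, w, grid: ColumnGrid, dt: float) -> tuple[np.ndarray, float]:
    """One upwind sinking step; returns (new concentration, bottom flux*dt).

    The bottom flux (units m^-2, already multiplied by dt) leaves the
    column and must be handed to the seafloor boundary.
    """
    flux = sinking_flux(conc, w, grid, dt=dt)
    influx = np.concatenate([[0.0], flux[:-1]])
    new = conc + dt * (influx - flux) / grid.layer_thickness
    return new, float(flux[-1] * dt)


def rise_flux(mp_free, F_R, w_p_day, grid: ColumnGrid) -> np.ndarray:
    """Upward upwind flux of the buoyant sub-population through layer tops.

    flux[i] is the flux from layer i into layer i-1 (particles m^-2 d^-1);
    flux[0] = 0 always: particles arriving in the surface layer accumulate
    there and never leave through the sea surface.
    """
    if not 0.0 <= F_R <= 1.0:
        raise ValueError("F_R must lie in [0, 1]")
    mp_free = np.asarray(mp_free, dtype=float)
    flux = F_R * w_p_day * mp_free
    flux[0] = 0.0
    return flux


def apply_rise(mp_free, F_R, w_p_day, grid: ColumnGrid, dt: float) -> np.ndarray:
    """Advect the rising fraction of free MP upward, sub-cycled for CFL.

    The buoyant sub-population F_R * MP_free is advected at w_p with as
    many internal sub-steps as its CFL limit requires; the remainder stays
    put. Conserves particles exactly.
    """
    mp_free = np.asarray(mp_free, dtype=float)
    if F_R == 0.0 or w_p_day == 0.0 or mp_free.size == 1:
        return mp_free.copy()
    rising = F_R * mp_free
    rest = mp_free - rising
    dz = grid.layer_thickness
    dz_min = float(dz[1:].min())
    n_sub = max(1, math.ceil(w_p_day * dt / dz_min))
    dt_sub = dt / n_sub
    for _ in range(n_sub):
        flux = w_p_day * rising  # upward, from layer i to i-1
        flux[0] = 0.0
        gain = np.concatenate([flux[1:], [0.0]])
        rising = rising + dt_sub * (gain - flux) / dz
    return rest + rising


def apply_diffusion(conc, grid: ColumnGrid, cfg: TransportConfig,
                    dt: float) -> np.ndarray:
    """Explicit vertical diffusion, conservative flux form."""
    conc = np.asarray(conc, dtype=float)
    n = conc.size
    if n == 1:
        return conc.copy()
    z_int = grid.interface_depth[:-1]
    kappa = np.where(z_int <= cfg.surface_mix_depth, cfg.kappa_surface, cfg.kappa_v)
    dz_c = np.diff(grid.layer_center)
    flux = -kappa * np.diff(conc) / dz_c  # downward-positive at interior interfaces
    full = np.concatenate([[0.0], flux, [0.0]])
    return conc + dt * (full[:-1] - full[1:]) / grid.layer_thickness


def seafloor_exchange(bottom_mpa: float, bottom_mpz: float, F_B: float,
                      ledger: SeafloorLedger) -> float:
    """Split the bound-MP bottom flux into returned and buried parts.

    Returns the particle amount (per m2) re-entering the bottom-layer
    free pool; the ledger records the permanent losses and the return.
    """
    if bottom_mpa < 0 or bottom_mpz < 0:
        raise ValueError("bottom fluxes must be non-negative")
    if not 0.0 <= F_B <= 1.0:
        raise ValueError("F_B must lie in [0, 1]")
    returned = F_B * (bottom_mpa + bottom_mpz)
    ledger.lost_MP_A += (1.0 - F_B) * bottom_mpa
    ledger.lost_MP_Z += (1.0 - F_B) * bottom_mpz
    ledger.returned += returned
    return returned


# --------------------------------------------------------------------------
# Annual diagnostics accumulated during the run
# --------------------------------------------------------------------------

_PROFILE_VARS = ("MP_free", "MP_A", "MP_Z", "N", "PH", "CO", "DZ", "Z",
                 "DET_A", "DET_Z", "temperature")
_SCALAR_VARS = (
    "a_upt_above", "p_upt_above",            # particles m^-2 d^-1
    "mpa_flux_130", "mpz_flux_130",          # particles m^-2 d^-1
    "deta_flux_130", "detz_flux_130",        # mmol N m^-2 d^-1
    "npp_above", "grazing_above",            # mmol N m^-2 d^-1
    "snow_prod_above", "pellet_prod_above",  # mmol N m^-2 d^-1
    "surface_mp_free", "surface_mp_total",   # particles m^-3
    "inventory_total", "inventory_free",     # particles m^-2
    "emission_rate",                         # particles m^-2 d^-1
)


class _AnnualAccumulator:
    def __init__(self, n_layers: int):
        self.n_layers = n_layers
        self.reset()

    def reset(self) -> None:
        self.n = 0
        self.profiles = {k: np.zeros(self.n_layers) for k in _PROFILE_VARS}
        self.scalars = dict.fromkeys(_SCALAR_VARS, 0.0)

    def add_profile(self, key: str, values: np.ndarray) -> None:
        self.profiles[key] += values

    def add_scalar(self, key: str, value: float) -> None:
        self.scalars[key] += value

    def mean(self) -> tuple[dict, dict]:
        n = max(self.n, 1)
        return ({k: v / n for k, v in self.profiles.items()},
                {k: v / n for k, v in self.scalars.items()})


@dataclass
class RunResult:
    """Annual-mean output of a column run plus the conservation audit."""

    years: np.ndarray
    profiles: dict[str, np.ndarray]     # name -> (n_years, n_layers)
    scalars: "pandas.DataFrame"         # one row per year
    grid: ColumnGrid
    params: MPParameters
    ledger: SeafloorLedger
    audit: dict[str, float]
    stable: bool = True
    failure: str | None = None

    def budget_error(self) -> float:
        """Relative error of the particle budget.

        (inventory + sediment loss - emission) / emission; zero for a
        perfectly closed budget, excluding logged clip deficits.
        """
        emitted = self.audit["cumulative_emission"]
        if emitted == 0.0:
            return abs(self.audit["final_inventory"] + self.ledger.lost_total)
        resid = (self.audit["final_inventory"] + self.ledger.lost_total
                 - emitted - self.audit["initial_inventory"])
        return resid / emitted

    def to_dataset(self) -> "xarray.Dataset":
        import xarray as xr

        coords = {"year": self.years, "layer_center": ("layer", self.grid.layer_center)}
        data = {k: (("year", "layer"), v) for k, v in self.profiles.items()}
        for col in self.scalars.columns:
            if col != "year":
                data[col] = (("year",), self.scalars[col].to_numpy())
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["layer_thickness_m"] = list(self.grid.layer_thickness)
        ds.attrs["cell_area_m2"] = self.grid.cell_area
        ds.attrs["stable"] = int(self.stable)
        for k, v in self.audit.items():
            ds.attrs[f"audit_{k}"] = v
        ds.attrs["seafloor_lost_MP_A"] = self.ledger.lost_MP_A
        ds.attrs["seafloor_lost_MP_Z"] = self.ledger.lost_MP_Z
        ds.attrs["seafloor_returned"] = self.ledger.returned
        return ds


class NumericalInstability(RuntimeError):
    """Raised when a tracer goes non-finite; feeds the ensemble filter."""


class Simulation:
    """One vertical water column with ecosystem and microplastic tracers.

    Parameters
    ----------
    grid : ColumnGrid
        Vertical geometry; ``cell_area`` scales absolute emission to
        concentration (a single global-mean column uses the global ocean
        area).
    mp_params : MPParameters
        The sampled MP parameter set.
    eco_params, transport : optional
        Ecosystem and transport constants (defaults are the package's
        stand-in calibration).
    scenario : TemperatureScenario
        Prescribed temperature forcing.
    emission_weight : float
        This column's share of the global MP input (weights across
        columns sum to 1).
    """

    def __init__(self, grid: ColumnGrid, mp_params: MPParameters,
                 scenario: "forcing_mod.TemperatureScenario",
                 eco_params: EcoParams | None = None,
                 transport: TransportConfig | None = None,
                 emission_weight: float = 1.0,
                 eco_on: bool = True,
                 forcing_base_tonnes: float = forcing_mod.BASE_TONNES,
                 forcing_growth_rate: float = forcing_mod.GROWTH_RATE,
                 forcing_start_year: int = forcing_mod.START_YEAR):
        self.grid = grid
        self.params = mp_params
        self.eco_params = eco_params or EcoParams()
        self.transport = transport or TransportConfig()
        self.scenario = scenario
        self.emission_weight = float(emission_weight)
        self.eco_on = eco_on
        self.forcing_base_tonnes = forcing_base_tonnes
        self.forcing_growth_rate = forcing_growth_rate
        self.forcing_start_year = forcing_start_year
        self.prefs = renormalise_preferences(mp_params.psi_MP)

        self.w_det = sinking_speed(grid, self.transport)
        bad = np.nonzero(self.w_det * self.transport.dt > grid.layer_thickness)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"CFL violation in layer {i}: sinking {self.w_det[i]:.1f} m/d "
                f"x dt {self.transport.dt} d exceeds {grid.layer_thickness[i]:.1f} m"
            )
        self.light = np.exp(-self.eco_params.light_atten * grid.layer_center)
        # export diagnosed at the interface nearest 130 m (second interface
        # on the default grid)
        self.idx_130 = int(np.argmin(np.abs(grid.interface_depth - 130.0)))
        self._above = slice(0, self.idx_130 + 1)

        self.eco = self._initial_eco_state()
        self.mp = MPState.zeros(grid.n_layers)
        self.ledger = SeafloorLedger()
        self.audit = {"cumulative_emission": 0.0, "initial_inventory": 0.0,
                      "eco_clip_deficit": 0.0, "mp_clip_deficit": 0.0,
                      "final_inventory": 0.0}

    def _initial_eco_state(self) -> EcoState:
        n = self.grid.n_layers
        z = self.grid.layer_center
        state = EcoState.zeros(n)
        state.N = 4.0 + 26.0 * (1.0 - np.exp(-z / 600.0))  # nutricline
        if self.eco_on:
            surf = np.exp(-z / 120.0)
            state.PH = 0.2 * surf
            state.CO = 0.1 * surf
            state.DZ = 0.05 * surf
            state.Z = 0.1 * surf
            state.DET_A = 0.02 * surf
            state.DET_Z = 0.02 * surf
        return state

    # -- single step -------------------------------------------------------

    def step(self, year: float, accum: _AnnualAccumulator | None = None,
             mp_active: bool = True) -> None:
        dt = self.transport.dt
        grid = self.grid
        T = self.scenario.temperature_at(year)

        # (1) ecosystem sources
        if self.eco_on:
            from .microplastic import mp_as_nitrogen
            mp_n = mp_as_nitrogen(self.mp.MP_free, self.params) if mp_active else 0.0
            self.eco, fluxes = step_ecosystem(self.eco, T, self.light, dt,
                                              self.eco_params, self.prefs,
                                              mp_as_N=mp_n)
            self.audit["eco_clip_deficit"] += fluxes.clip_deficit
        else:
            from .ecosystem import EcoFluxes, remin_rate
            zeros = np.zeros(grid.n_layers)
            fluxes = EcoFluxes(det_a_source=zeros, pellet_production=zeros,
                               mu_D=remin_rate(T, self.eco_params), npp=zeros,
                               grazing_food=zeros, grazing_mp_n=zeros)

        # (2) MP sources and sinks
        if mp_active:
            tonnes = forcing_mod.waste_generation(
                year, base_tonnes=self.forcing_base_tonnes,
                growth_rate=self.forcing_growth_rate,
                start_year=self.forcing_start_year)
            emis_per_yr = (self.emission_weight * self.params.F_T
                           * tonnes * PARTICLES_PER_TONNE)
            emis_conc = np.zeros(grid.n_layers)
            emis_conc[0] = emis_per_yr / grid.cell_area / grid.layer_thickness[0] / DAYS_PER_YEAR
            tend = mp_tendencies(self.mp, self.eco, fluxes, self.prefs, T,
                                 self.params, self.eco_params, emis_conc, dt=dt)
            self.audit["cumulative_emission"] += emis_conc[0] * grid.layer_thickness[0] * dt

            mp_free = self.mp.MP_free + dt * tend.d_free
            mp_a = self.mp.MP_A + dt * tend.d_A
            mp_z = self.mp.MP_Z + dt * tend.d_Z
            for arr in (mp_free, mp_a, mp_z):
                neg = arr < 0
                if neg.any():
                    self.audit["mp_clip_deficit"] += float(
                        -(arr[neg] * grid.layer_thickness[neg]).sum())
                    arr[neg] = 0.0
        else:
            tend = None
            mp_free, mp_a, mp_z = self.mp.MP_free, self.mp.MP_A, self.mp.MP_Z

        # (3) transport
        if self.eco_on:
            self.eco.DET_A, bot_a = apply_sinking(self.eco.DET_A, self.w_det, grid, dt)
            self.eco.DET_Z, bot_z = apply_sinking(self.eco.DET_Z, self.w_det, grid, dt)
            # detritus reaching the seafloor is remineralised to bottom nutrient
            self.eco.N[-1] += (bot_a + bot_z) / grid.layer_thickness[-1]
            for name in ("N", "PH", "CO", "DZ", "Z", "DET_A", "DET_Z"):
                setattr(self.eco, name,
                        apply_diffusion(getattr(self.eco, name), grid,
                                        self.transport, dt))
        if mp_active:
            mp_a, bot_mpa = apply_sinking(mp_a, self.w_det, grid, dt)
            mp_z, bot_mpz = apply_sinking(mp_z, self.w_det, grid, dt)
            mp_free = apply_rise(mp_free, self.params.F_R,
                                 self.params.w_p_m_per_day, grid, dt)
            mp_free = apply_diffusion(mp_free, grid, self.transport, dt)
            mp_a = apply_diffusion(mp_a, grid, self.transport, dt)
            mp_z = apply_diffusion(mp_z, grid, self.transport, dt)

            # (4) seafloor boundary
            returned = seafloor_exchange(bot_mpa, bot_mpz, self.params.F_B,
                                         self.ledger)
            mp_free[-1] += returned / grid.layer_thickness[-1]
            self.mp = MPState(mp_free, mp_a, mp_z)

        if not np.isfinite(self.mp.MP_free.sum() + self.eco.N.sum()):
            raise NumericalInstability(f"non-finite tracer at year {year:.2f}")

        if accum is not None and tend is not None:
            self._accumulate(accum, T, fluxes, tend)

    def _accumulate(self, accum, T, fluxes, tend) -> None:
        grid = self.grid
        dz_above = grid.layer_thickness[self._above]
        accum.n += 1
        for key, arr in (("MP_free", self.mp.MP_free), ("MP_A", self.mp.MP_A),
                         ("MP_Z", self.mp.MP_Z), ("N", self.eco.N),
                         ("PH", self.eco.PH), ("CO", self.eco.CO),
                         ("DZ", self.eco.DZ), ("Z", self.eco.Z),
                         ("DET_A", self.eco.DET_A), ("DET_Z", self.eco.DET_Z),
                         ("temperature", T)):
            accum.add_profile(key, arr)
        s = accum.add_scalar
        s("a_upt_above", float(np.sum(tend.A_upt[self._above] * dz_above)))
        s("p_upt_above", float(np.sum(tend.P_upt[self._above] * dz_above)))
        w130 = self.w_det[self.idx_130]
        s("mpa_flux_130", w130 * self.mp.MP_A[self.idx_130])
        s("mpz_flux_130", w130 * self.mp.MP_Z[self.idx_130])
        s("deta_flux_130", w130 * self.eco.DET_A[self.idx_130])
        s("detz_flux_130", w130 * self.eco.DET_Z[self.idx_130])
        s("npp_above", float(np.sum(fluxes.npp[self._above] * dz_above)))
        s("grazing_above", float(np.sum(fluxes.grazing_food[self._above] * dz_above)))
        s("snow_prod_above", float(np.sum(fluxes.det_a_source[self._above] * dz_above)))
        s("pellet_prod_above",
          float(np.sum(fluxes.pellet_production[self._above] * dz_above)))
        s("surface_mp_free", self.mp.MP_free[0])
        s("surface_mp_total", self.mp.total()[0])
        s("inventory_total", self.mp.column_total(grid.layer_thickness))
        s("inventory_free", float(np.sum(self.mp.MP_free * grid.layer_thickness)))
        s("emission_rate", self.audit["cumulative_emission"])  # overwritten below

    # -- run loop ----------------------------------------------------------

    def run(self, start_year: int = 1950, end_year: int = 2020,
            spinup_years: int = 20) -> RunResult:
        """Spin the ecosystem up, then integrate with MP forcing.

        Returns annual-mean diagnostics for calendar years
        ``start_year .. end_year - 1``.
        """
        import pandas as pd

        dt = self.transport.dt
        steps_per_year = int(round(DAYS_PER_YEAR / dt))
        failure = None
        accum = _AnnualAccumulator(self.grid.n_layers)
        years, prof_rows, scalar_rows = [], [], []
        try:
            for y in range(spinup_years):
                year = start_year - spinup_years + y
                for k in range(steps_per_year):
                    self.step(year + k * dt / DAYS_PER_YEAR, mp_active=False)
            for year in range(start_year, end_year):
                accum.reset()
                emis_before = self.audit["cumulative_emission"]
                for k in range(steps_per_year):
                    self.step(year + k * dt / DAYS_PER_YEAR, accum=accum)
                profs, scal = accum.mean()
                scal["emission_rate"] = (self.audit["cumulative_emission"]
                                         - emis_before) / DAYS_PER_YEAR
                years.append(year)
                prof_rows.append(profs)
                scalar_rows.append(scal)
            stable = True
        except NumericalInstability as exc:
            failure = str(exc)
            stable = False

        self.audit["final_inventory"] = self.mp.column_total(self.grid.layer_thickness)
        n_y = len(years)
        profiles = {
            k: np.array([row[k] for row in prof_rows]).reshape(n_y, self.grid.n_layers)
            for k in _PROFILE_VARS
        }
        scalars = pd.DataFrame(scalar_rows)
        scalars.insert(0, "year", years)
        return RunResult(years=np.asarray(years), profiles=profiles,
                         scalars=scalars, grid=self.grid, params=self.params,
                         ledger=self.ledger, audit=dict(self.audit),
                         stable=stable, failure=failure)


def run_simulation(config, years: tuple[int, int] | None = None) -> RunResult:
    """Run a column simulation from a :class:`~mpsink.config.RunConfig`."""
    sim = config.build_simulation()
    start, end = years if years is not None else (config.start_year, config.end_year)
    return sim.run(start_year=start, end_year=end,
                   spinup_years=config.spinup_years)
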