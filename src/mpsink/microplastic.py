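"""Sources and sinks of the three microplastic compartments.

Free microplastic (``MP_free``) is exchanged with two biologically bound
pools: MP aggregated in marine snow (``MP_A``) and MP in zooplankton
faecal pellets (``MP_Z``). Uptake into marine snow follows a Monod
(saturating) function of the free-MP concentration applied to the rate of
marine-snow formation; uptake into pellets follows the extended Holling
type-II grazing with MP as a prey item. Both bound pools release particles
back to the free pool at the temperature-dependent detrital
remineralisation rate. All MP tracers are particle counts (particles/m3);
the grazing calculation converts particles -> g MP -> g food -> mmol N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecosystem import EcoFluxes, EcoParams, EcoState, PreferenceSet, grazing_rates
from .params import (GRAMS_PER_PARTICLE, MPParameters, PARTICLES_PER_TONNE,
                     REDFIELD_C_N, UG_C_PER_AGGREGATE)

__all__ = [
    "MPState",
    "mass_to_particles",
    "particles_to_mass",
    "aggregate_count",
    "aggregation_uptake",
    "aggregate_release",
    "mp_as_nitrogen",
    "mp_grazing",
    "pellet_release",
    "mp_tendencies",
    "MPTendencies",
]


@dataclass
class MPState:
    """Per-layer MP concentrations (particles m^-3) for the three pools."""

    MP_free: np.ndarray
    MP_A: np.ndarray
    MP_Z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("MP_free", "MP_A", "MP_Z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative {name}")
            setattr(self, name, arr)

    @classmethod
    def zeros(cls, n_layers: int) -> "MPState":
        return cls(np.zeros(n_layers), np.zeros(n_layers), np.zeros(n_layers))

    def copy(self) -> "MPState":
        return MPState(self.MP_free.copy(), self.MP_A.copy(), self.MP_Z.copy())

    def total(self) -> np.ndarray:
        return self.MP_free + self.MP_A + self.MP_Z

    def column_total(self, thickness: np.ndarray) -> float:
        """Column inventory, particles m^-2."""
        return float(np.sum(self.total() * thickness))


def mass_to_particles(mass_tonnes):
    """Convert MP mass (tonnes) to particle count (236e3 t == 51.2e12)."""
    mass_tonnes = np.asarray(mass_tonnes, dtype=float)
    if np.any(mass_tonnes < 0):
        raise ValueError("mass must be non-negative")
    out = mass_tonnes * PARTICLES_PER_TONNE
    return float(out) if out.ndim == 0 else out


def particles_to_mass(particles):
    """Inverse conversion: particle count to MP mass in tonnes."""
    particles = np.asarray(particles, dtype=float)
    if np.any(particles < 0):
        raise ValueError("particle count must be non-negative")
    out = particles / PARTICLES_PER_TONNE
    return float(out) if out.ndim == 0 else out


def aggregate_count(det_source, ug_c_per_aggregate: float = UG_C_PER_AGGREGATE):
    """Maximum number of new aggregates formed per m3 per day.

    Marine-snow production in mmol N m^-3 d^-1 is converted to carbon via
    Redfield stoichiometry (106:16) and divided by the characteristic
    carbon content of one aggregate (ug C): each new aggregate can carry
    at most one MP particle.
    """
    det_source = np.asarray(det_source, dtype=float)
    out = det_source * REDFIELD_C_N * 12.011e3 / ug_c_per_aggregate
    return float(out) if out.ndim == 0 else out


def aggregation_uptake(mp_free, det_source, k_P: float, F_A: float):
    """Monod uptake of free MP into newly forming marine snow (A_upt).

    A_upt = MP/(k_P + MP) x aggregate_count(det_source) x F_A, in
    particles m^-3 d^-1; bounded above by F_A x aggregate_count. With
    k_P = 0 and MP = 0 the Monod factor is taken as 0.
    """
    mp_free = np.asarray(mp_free, dtype=float)
    denom = k_P + mp_free
    with np.errstate(divide="ignore", invalid="ignore"):
        monod = np.where(denom > 0, mp_free / np.maximum(denom, 1e-300), 0.0)
    out = monod * aggregate_count(det_source) * F_A
    return float(out) if out.ndim == 0 else out


def aggregate_release(mp_a, mu_D):
    """Release of MP from marine snow at the remineralisation rate (A_rel)."""
    out = np.asarray(mu_D, dtype=float) * np.asarray(mp_a, dtype=float)
    return float(out) if out.ndim == 0 else out


def pellet_release(mp_z, mu_D):
    """Release of MP from faecal pellets (P_rel), same rate as aggregates."""
    out = np.asarray(mu_D, dtype=float) * np.asarray(mp_z, dtype=float)
    return float(out) if out.ndim == 0 else out


def mp_as_nitrogen(mp_free, params: MPParameters):
    """Free-MP concentration expressed in the grazing currency (mmol N m^-3)."""
    out = np.asarray(mp_free, dtype=float) * params.mp_particle_to_mmol_n
    return float(out) if out.ndim == 0 else out


def mp_grazing(mp_free, state: EcoState, prefs: PreferenceSet, T,
               params: MPParameters, eco_params: EcoParams):
    """Zooplankton uptake of MP particles, P_upt (particles m^-3 d^-1).

    The grazing of MP (G_MP) is computed in nitrogen units through the
    extended Holling-II response, then converted back to particles by the
    same mass/food/nitrogen conversion chain.
    """
    mp_n = mp_as_nitrogen(mp_free, params)
    g = grazing_rates(state, prefs, T, eco_params, mp_as_N=mp_n)
    conv = params.mp_particle_to_mmol_n
    if conv == 0.0:
        return np.zeros_like(np.asarray(mp_free, dtype=float))
    out = g["MP"] / conv
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class MPTendencies:
    """Per-layer source-minus-sink tendencies (particles m^-3 d^-1)."""

    d_free: np.ndarray
    d_A: np.ndarray
    d_Z: np.ndarray
    A_upt: np.ndarray
    P_upt: np.ndarray
    A_rel: np.ndarray
    P_rel: np.ndarray


def mp_tendencies(mp: MPState, eco_state: EcoState, eco_fluxes: EcoFluxes,
                  prefs: PreferenceSet, T, params: MPParameters,
                  eco_params: EcoParams, emission,
                  dt: float | None = None) -> MPTendencies:
    """Source/sink tendencies for the three MP pools (no transport).

    ``emission`` is the per-layer emission rate in particles m^-3 d^-1
    (all of it in the surface layer for a standard run). When ``dt`` is
    given, uptake sinks are scaled so the step cannot remove more free MP
    than is present. The three tendencies sum to the emission exactly:
    exchange terms cancel pairwise.
    """
    n = mp.MP_free.size
    emission = np.broadcast_to(np.asarray(emission, dtype=float), (n,))
    T = np.asarray(T, dtype=float)
    if not (mp.MP_A.size == mp.MP_Z.size == n == eco_fluxes.mu_D.size):
        raise ValueError("mismatched layer counts")

    a_upt = np.asarray(aggregation_uptake(mp.MP_free, eco_fluxes.det_a_source,
                                          params.k_P, params.F_A))
    p_upt = np.asarray(mp_grazing(mp.MP_free, eco_state, prefs, T,
                                  params, eco_params))
    if dt is not None and dt > 0:
        total_upt = a_upt + p_upt
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(total_upt * dt > mp.MP_free,
                         mp.MP_free / np.maximum(total_upt * dt, 1e-300), 1.0)
        s = np.clip(s, 0.0, 1.0)
        a_upt, p_upt = a_upt * s, p_upt * s

    a_rel = np.asarray(aggregate_release(mp.MP_A, eco_fluxes.mu_D))
    p_rel = np.asarray(pellet_release(mp.MP_Z, eco_fluxes.mu_D))
    if dt is not None and dt > 0:
        a_rel = np.minimum(a_rel, mp.MP_A / dt)
        p_rel = np.minimum(p_rel, mp.MP_Z / dt)

    d_free = emission - a_upt - p_upt + a_rel + p_rel
    d_a = a_upt - a_rel
    d_z = p_upt - p_rel
    return MPTendencies(d_free=d_free, d_A=d_a, d_Z=d_z,
                        A_upt=a_upt, P_upt=p_upt, A_rel=a_rel, P_rel=p_rel)
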