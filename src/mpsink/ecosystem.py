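"""Minimal NPZD-style plankton ecosystem for the water column.

This supplies the biological rates the microplastic equations consume:
marine-snow (free detritus) production, faecal-pellet production,
temperature-dependent remineralisation, Holling type-II multi-prey
grazing, and net primary production. The full ocean biogeochemistry it
stands in for is far richer; only the interfaces matter here, so the
functional forms are deliberately simple: light x nutrient-limited Monod
growth with Eppley temperature scaling, linear phytoplankton mortality,
and linear + quadratic zooplankton mortality.

Tracers (mmol N m^-3 per layer):

* ``N``     dissolved nutrient
* ``PH``    mixed phytoplankton
* ``CO``    small phytoplankton / calcifiers (no calcite tracer is carried)
* ``DZ``    diazotrophs (a poor food source; grazing preference fixed 0.1)
* ``Z``     zooplankton
* ``DET_A`` free detritus = marine snow
* ``DET_Z`` faecal-pellet detritus

Half of zooplankton particulate losses are diverted into the pellet pool;
both detritus classes share the same sinking law, so their sum evolves
exactly as a single-detritus model would.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EcoParams",
    "EcoState",
    "EcoFluxes",
    "PreferenceSet",
    "renormalise_preferences",
    "remin_rate",
    "max_growth",
    "grazing_rates",
    "step_ecosystem",
]

PSI_DZ_FIXED = 0.1


@dataclass(frozen=True)
class EcoParams:
    """Rate constants (all rates per day, concentrations mmol N m^-3).

    The detrital constants ``mu_D0`` and ``q10_remin`` (with the sinking
    law in the transport configuration) set the particle export
    efficiency of the column; see docs/methods.md for how their defaults
    were chosen.
    """

    mu_P0: float = 0.6          # phytoplankton max growth at 0 degC
    eppley_b: float = 1.066     # Eppley temperature base (per degC)
    k_N: float = 0.7            # nutrient half-saturation
    co_handicap: float = 0.9    # growth factor for small phyto/calcifiers
    dz_handicap: float = 0.5    # growth factor for diazotrophs
    mort_P: float = 0.05        # linear phytoplankton mortality
    mu_Z_max0: float = 0.6      # zoo max grazing at 0 degC
    zoo_cap_C: float = 20.0     # temperature cap for zoo max growth
    k_Z: float = 0.15           # grazing half-saturation
    assim_eff: float = 0.7      # assimilated fraction of grazed food
    excretion: float = 0.03     # linear zoo excretion (dissolved loss)
    mort_Z: float = 0.06        # linear zoo mortality (particulate)
    quad_Z: float = 0.25        # quadratic zoo mortality ((mmol N m^-3)^-1 d^-1)
    mu_D0: float = 0.10         # detrital remineralisation at 0 degC
    q10_remin: float = 1.5      # remineralisation Q10
    pellet_fraction: float = 0.5  # share of zoo particulate losses to pellets
    light_atten: float = 0.04   # PAR attenuation (m^-1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pellet_fraction <= 1.0:
            raise ValueError("pellet_fraction outside [0, 1]")
        for name in ("mu_P0", "mu_Z_max0", "k_Z", "k_N", "mu_D0", "q10_remin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_TRACERS = ("N", "PH", "CO", "DZ", "Z", "DET_A", "DET_Z")


@dataclass
class EcoState:
    """Per-layer ecosystem tracer concentrations (mmol N m^-3)."""

    N: np.ndarray
    PH: np.ndarray
    CO: np.ndarray
    DZ: np.ndarray
    Z: np.ndarray
    DET_A: np.ndarray
    DET_Z: np.ndarray

    def __post_init__(self) -> None:
        for name in _TRACERS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative {name} concentration")
            setattr(self, name, arr)

    @classmethod
    def zeros(cls, n_layers: int) -> "EcoState":
        return cls(*[np.zeros(n_layers) for _ in _TRACERS])

    def copy(self) -> "EcoState":
        return EcoState(*[getattr(self, t).copy() for t in _TRACERS])

    def total_nitrogen(self, thickness: np.ndarray) -> float:
        """Column-integrated nitrogen over all pools (mmol N m^-2)."""
        tot = 0.0
        for t in _TRACERS:
            tot += float(np.sum(getattr(self, t) * thickness))
        return tot


@dataclass(frozen=True)
class PreferenceSet:
    """Grazing preferences; must sum to 1 including the MP term."""

    psi_CO: float
    psi_PH: float
    psi_DZ: float
    psi_Detr: float
    psi_Z: float
    psi_MP: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.psi_CO, self.psi_PH, self.psi_DZ, self.psi_Detr,
                self.psi_Z, self.psi_MP)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("preferences must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-8:
            raise ValueError(f"preferences sum to {sum(vals):.8f}, expected 1")


def renormalise_preferences(psi_MP: float) -> PreferenceSet:
    """Preference set for a given MP preference.

    Diazotrophs keep a fixed preference of 0.1 (a poor food source whose
    grazing pressure should not be perturbed); the remaining allowance
    1 - 0.1 - psi_MP is split equally among the other four prey classes.
    """
    if not 0.0 <= psi_MP <= 0.9:
        raise ValueError("psi_MP must lie in [0, 0.9]")
    rest = (1.0 - PSI_DZ_FIXED - psi_MP) / 4.0
    return PreferenceSet(psi_CO=rest, psi_PH=rest, psi_DZ=PSI_DZ_FIXED,
                         psi_Detr=rest, psi_Z=rest, psi_MP=psi_MP)


def remin_rate(T, params: EcoParams):
    """Detrital remineralisation rate mu_D(T) = mu_D0 * Q10^(T/10) (d^-1)."""
    return params.mu_D0 * params.q10_remin ** (np.asarray(T, dtype=float) / 10.0)


def max_growth(T, params: EcoParams):
    """Zooplankton maximum grazing rate (d^-1), capped above 20 degC.

    Eppley-type increase with temperature up to the cap, flat above it,
    representing metabolic limitation of growth in very warm water.
    """
    T_eff = np.minimum(np.asarray(T, dtype=float), params.zoo_cap_C)
    return params.mu_Z_max0 * params.eppley_b ** T_eff


def _holling_denominator(state: EcoState, prefs: PreferenceSet,
                         mp_as_N, params: EcoParams):
    detr_tot = state.DET_A + state.DET_Z
    return (prefs.psi_CO * state.CO + prefs.psi_PH * state.PH
            + prefs.psi_DZ * state.DZ + prefs.psi_Detr * detr_tot
            + prefs.psi_Z * state.Z + prefs.psi_MP * np.asarray(mp_as_N)
            + params.k_Z)


def grazing_rates(state: EcoState, prefs: PreferenceSet, T,
                  params: EcoParams, mp_as_N=0.0) -> dict[str, np.ndarray]:
    """Holling type-II grazing on every prey, extended with an MP term.

    ``mp_as_N`` is the free-MP concentration expressed in the grazing
    currency (mmol N m^-3). Returns per-prey grazing rates
    (mmol N m^-3 d^-1) keyed 'CO','PH','DZ','Detr','Z','MP'; total
    grazing is bounded by mu_Z_max(T) * Z.
    """
    mu = max_growth(T, params) * state.Z
    denom = _holling_denominator(state, prefs, mp_as_N, params)
    detr_tot = state.DET_A + state.DET_Z
    return {
        "CO": mu * prefs.psi_CO * state.CO / denom,
        "PH": mu * prefs.psi_PH * state.PH / denom,
        "DZ": mu * prefs.psi_DZ * state.DZ / denom,
        "Detr": mu * prefs.psi_Detr * detr_tot / denom,
        "Z": mu * prefs.psi_Z * state.Z / denom,
        "MP": mu * prefs.psi_MP * np.asarray(mp_as_N, dtype=float) / denom,
    }


@dataclass
class EcoFluxes:
    """Per-layer biological fluxes the MP equations and diagnostics consume.

    All in mmol N m^-3 d^-1 except ``mu_D`` (d^-1).
    """

    det_a_source: np.ndarray      # marine-snow (free detritus) production
    pellet_production: np.ndarray  # faecal-pellet detritus production
    mu_D: np.ndarray              # remineralisation rate
    npp: np.ndarray               # net primary production
    grazing_food: np.ndarray      # total grazing on food prey (not MP)
    grazing_mp_n: np.ndarray      # MP grazing in nitrogen currency
    clip_deficit: float = 0.0     # nitrogen clipped to keep tracers >= 0


def step_ecosystem(state: EcoState, T, light, dt: float, params: EcoParams,
                   prefs: PreferenceSet, mp_as_N=0.0) -> tuple[EcoState, EcoFluxes]:
    """Advance the ecosystem one explicit Euler step (sources only).

    ``light`` is the dimensionless per-layer light limitation factor.
    Sinks are scaled so no pool is overdrawn within ``dt`` (the residual
    after scaling is clipped and logged). Nitrogen is conserved: every
    loss term is a gain somewhere else.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = np.asarray(T, dtype=float)
    light = np.asarray(light, dtype=float)

    # --- raw fluxes -------------------------------------------------------
    t_fac = params.eppley_b ** T
    nut = state.N / (params.k_N + state.N)
    npp_PH = params.mu_P0 * t_fac * light * nut * state.PH
    npp_CO = params.mu_P0 * params.co_handicap * t_fac * light * nut * state.CO
    npp_DZ = params.mu_P0 * params.dz_handicap * t_fac * light * nut * state.DZ

    graz = grazing_rates(state, prefs, T, params, mp_as_N)

    mort_PH = params.mort_P * state.PH
    mort_CO = params.mort_P * state.CO
    mort_DZ = params.mort_P * state.DZ
    mort_Zl = params.mort_Z * state.Z + params.quad_Z * state.Z**2
    excr = params.excretion * state.Z

    mu_D = remin_rate(T, params)
    remin_A = mu_D * state.DET_A
    remin_Z = mu_D * state.DET_Z

    # --- limiters: scale sinks so no pool is overdrawn within dt ----------
    def scale(pool, *sinks):
        total = sum(sinks)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(total * dt > pool, pool / np.maximum(total * dt, 1e-300), 1.0)
        return np.clip(s, 0.0, 1.0)

    s_N = scale(state.N, npp_PH + npp_CO + npp_DZ)
    npp_PH, npp_CO, npp_DZ = npp_PH * s_N, npp_CO * s_N, npp_DZ * s_N

    s_PH = scale(state.PH, graz["PH"] + mort_PH)
    s_CO = scale(state.CO, graz["CO"] + mort_CO)
    s_DZ = scale(state.DZ, graz["DZ"] + mort_DZ)
    graz["PH"], mort_PH = graz["PH"] * s_PH, mort_PH * s_PH
    graz["CO"], mort_CO = graz["CO"] * s_CO, mort_CO * s_CO
    graz["DZ"], mort_DZ = graz["DZ"] * s_DZ, mort_DZ * s_DZ

    s_Z = scale(state.Z, graz["Z"] + mort_Zl + excr)
    graz["Z"], mort_Zl, excr = graz["Z"] * s_Z, mort_Zl * s_Z, excr * s_Z

    detr_tot = state.DET_A + state.DET_Z
    with np.errstate(divide="ignore", invalid="ignore"):
        share_A = np.where(detr_tot > 0, state.DET_A / np.maximum(detr_tot, 1e-300), 0.0)
    graz_DET_A = graz["Detr"] * share_A
    graz_DET_Z = graz["Detr"] * (1.0 - share_A)
    s_DA = scale(state.DET_A, graz_DET_A + remin_A)
    s_DZ2 = scale(state.DET_Z, graz_DET_Z + remin_Z)
    graz_DET_A, remin_A = graz_DET_A * s_DA, remin_A * s_DA
    graz_DET_Z, remin_Z = graz_DET_Z * s_DZ2, remin_Z * s_DZ2

    # --- assemble tendencies ---------------------------------------------
    graz_food = (graz["PH"] + graz["CO"] + graz["DZ"] + graz["Z"]
                 + graz_DET_A + graz_DET_Z)
    unassim = (1.0 - params.assim_eff) * graz_food
    particulate_Z = unassim + mort_Zl
    pellet_prod = params.pellet_fraction * particulate_Z
    snow_from_Z = (1.0 - params.pellet_fraction) * particulate_Z
    det_a_source = mort_PH + mort_CO + mort_DZ + snow_from_Z

    npp = npp_PH + npp_CO + npp_DZ
    dN = -npp + excr + remin_A + remin_Z
    dPH = npp_PH - mort_PH - graz["PH"]
    dCO = npp_CO - mort_CO - graz["CO"]
    dDZ = npp_DZ - mort_DZ - graz["DZ"]
    dZ = params.assim_eff * graz_food - graz["Z"] - mort_Zl - excr
    dDET_A = det_a_source - graz_DET_A - remin_A
    dDET_Z = pellet_prod - graz_DET_Z - remin_Z

    new = state.copy()
    deficit = 0.0
    for name, tend in (("N", dN), ("PH", dPH), ("CO", dCO), ("DZ", dDZ),
                       ("Z", dZ), ("DET_A", dDET_A), ("DET_Z", dDET_Z)):
        arr = getattr(new, name) + dt * tend
        neg = np.minimum(arr, 0.0)
        deficit += float(-neg.sum())
        setattr(new, name, np.maximum(arr, 0.0))

    fluxes = EcoFluxes(det_a_source=det_a_source, pellet_production=pellet_prod,
                       mu_D=mu_D, npp=npp, grazing_food=graz_food,
                       grazing_mp_n=graz["MP"], clip_deficit=deficit)
    return new, fluxes
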