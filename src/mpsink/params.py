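"""Microplastic parameter sets, physical constants, and the packaged fixtures.

The seven sampled parameters control how strongly the biology interacts
with microplastic (MP):

==========  =====================================================  =========
name        meaning                                                range
==========  =====================================================  =========
F_T         fraction of annual plastic waste entering as MP        0 - 1
F_R         fraction of free MP assigned a fast rise rate          0 - 0.1
F_A         fraction of new marine snow that aggregates MP         0 - 1
k_P         MP/marine-snow uptake half-saturation (particles/m3)   0 - 1000
F_B         fraction of seafloor MP flux returned to the water     0 - 1
psi_MP      zooplankton grazing preference for MP                  0.1 - 0.3
R_F_MP      food:MP substitution ratio (g food per g MP)           0.5 - 1.5
==========  =====================================================  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MPParameters",
    "FIXTURES",
    "fixture",
    "PARTICLES_PER_TONNE",
    "GRAMS_PER_PARTICLE",
    "REDFIELD_C_N",
    "R_N_F",
    "UG_C_PER_AGGREGATE",
]

# Mass <-> particle conversion: 236e3 tonnes MP == 51.2e12 particles MP.
PARTICLES_PER_TONNE = 51.2e12 / 236.0e3
GRAMS_PER_PARTICLE = 236.0e9 / 51.2e12  # ~4.609e-3 g per particle

# Redfield C:N (106:16) for detrital nitrogen -> carbon conversion.
REDFIELD_C_N = 106.0 / 16.0

# mol N per gram of Redfield organic food (C106 H263 O110 N16 P weighs
# ~3553 g per 16 mol N -> 222.1 g per mol N).
R_N_F = 1.0 / 222.1

# Characteristic carbon content of a freshly formed (diatom-like) marine
# snow aggregate.
UG_C_PER_AGGREGATE = 8.8

_RANGES = {
    "F_T": (0.0, 1.0),
    "F_R": (0.0, 0.1),
    "F_A": (0.0, 1.0),
    "k_P": (0.0, 1000.0),
    "F_B": (0.0, 1.0),
    "psi_MP": (0.1, 0.3),
    "R_F_MP": (0.5, 1.5),
}


@dataclass(frozen=True)
class MPParameters:
    """The 7 sampled MP parameters plus fixed physical constants."""

    F_T: float = 0.0
    F_R: float = 0.0
    F_A: float = 0.0
    k_P: float = 1.0
    F_B: float = 0.0
    psi_MP: float = 0.0
    R_F_MP: float = 1.0
    #: fast rise speed of positively buoyant free MP (m/s)
    w_p: float = 0.019
    #: grams of MP per particle (mass<->particle conversion)
    grams_per_particle: float = GRAMS_PER_PARTICLE
    #: mol N per g food for the food-substitution conversion
    r_n_f: float = R_N_F
    #: ug C per newly formed aggregate
    ug_c_per_aggregate: float = UG_C_PER_AGGREGATE

    def __post_init__(self) -> None:
        for name in ("F_T", "F_R", "F_A", "F_B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.k_P < 0:
            raise ValueError("k_P must be non-negative")
        if not 0.0 <= self.psi_MP <= 0.9:
            raise ValueError("psi_MP outside [0, 0.9]")
        if self.R_F_MP < 0:
            raise ValueError("R_F_MP must be non-negative")

    @property
    def w_p_m_per_day(self) -> float:
        return self.w_p * 86400.0

    @property
    def mp_particle_to_mmol_n(self) -> float:
        """mmol N represented by one MP particle/m3 in the grazing currency.

        particles -> g MP -> g food (R_F:MP) -> mol N (R_N:F) -> mmol N.
        """
        return self.grams_per_particle * self.R_F_MP * self.r_n_f * 1.0e3

    def with_values(self, **kwargs) -> "MPParameters":
        return replace(self, **kwargs)

    @staticmethod
    def sampling_range(name: str) -> tuple[float, float]:
        return _RANGES[name]


# Sample parameterisations (simulation name -> sampled parameter values).
# The biological parameters of the no-biology configuration are inactive.
FIXTURES: dict[str, MPParameters] = {
    "no_bio": MPParameters(F_T=0.260, F_R=0.033, F_A=0.0, k_P=1.0, F_B=0.0,
                           psi_MP=0.0, R_F_MP=1.0),
    "test_lo": MPParameters(F_T=0.137, F_R=0.003, F_B=0.132, F_A=0.003,
                            k_P=0.424, psi_MP=0.260, R_F_MP=1.029),
    "test_hi": MPParameters(F_T=0.329, F_R=0.074, F_B=0.888, F_A=0.098,
                            k_P=833.290, psi_MP=0.132, R_F_MP=1.489),
    "test_med": MPParameters(F_T=0.276, F_R=0.011, F_B=0.528, F_A=0.092,
                             k_P=615.508, psi_MP=0.193, R_F_MP=0.993),
}


def fixture(name: str) -> MPParameters:
    """Return a packaged sample parameterisation by name."""
    key = name.lower().replace("-", "_")
    if key not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return FIXTURES[key]
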