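"""Plastic-waste forcing and prescribed temperature scenarios.

Global plastic waste generation starts at 2 million tonnes per year in 1950
and grows at 8.4 % per year (annually compounded; the forcing is defined
per calendar year and held piecewise-constant within a year). A fraction
F_T of that waste enters the ocean as microplastic, converted from tonnes
to particles and distributed over the columns by a non-negative weight
vector that sums to one.

Ocean temperature is prescribed, not simulated: each column carries a base
profile plus an optional idealised linear warming trend applied to the
upper ocean after year 2000. This stands in for a coupled high-emission
warming projection so that the temperature-dependent rates (growth,
grazing, remineralisation) can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ColumnGrid
from .params import MPParameters, PARTICLES_PER_TONNE

__all__ = [
    "BASE_TONNES",
    "GROWTH_RATE",
    "START_YEAR",
    "waste_generation",
    "mp_emission",
    "TemperatureScenario",
    "temperature_profile",
    "forcing_table",
]

BASE_TONNES = 2.0e6
GROWTH_RATE = 0.084
START_YEAR = 1950


def waste_generation(year, base_tonnes: float = BASE_TONNES,
                     growth_rate: float = GROWTH_RATE,
                     start_year: int = START_YEAR):
    """Global plastic waste generation (tonnes/yr) for a (fractional) year.

    Zero before ``start_year``; annually compounded growth afterwards,
    piecewise-constant within each calendar year.
    """
    year = np.asarray(year)
    n = np.floor(year).astype(int) - start_year
    out = np.where(n >= 0, base_tonnes * (1.0 + growth_rate) ** np.maximum(n, 0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def mp_emission(year, params: MPParameters, weights) -> np.ndarray:
    """Per-column MP emission rate (particles/yr) for a given year.

    ``weights`` distribute the global input over columns; they must be
    non-negative and sum to 1. All emission enters the surface layer of
    the receiving column.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("emission weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError(f"emission weights sum to {weights.sum():.6g}, expected 1")
    total = params.F_T * waste_generation(year) * PARTICLES_PER_TONNE
    return weights * total


def temperature_profile(grid: ColumnGrid, surface_C: float,
                        deep_C: float = 2.0, efold_m: float = 250.0,
                        mixed_layer_m: float = 50.0) -> np.ndarray:
    """An idealised thermocline: a warm mixed layer at ``surface_C``, then
    exponential decay towards ``deep_C``."""
    z = np.maximum(grid.layer_center - mixed_layer_m, 0.0)
    return deep_C + (surface_C - deep_C) * np.exp(-z / efold_m)


@dataclass
class TemperatureScenario:
    """Prescribed per-layer temperature with an optional warming trend.

    The trend (degC per century) applies after ``trend_start`` to layers
    whose centre is shallower than ``full_trend_depth_m``, decaying
    e-fold below that; temperatures are clamped to the physical range
    [-2, 35] degC.
    """

    base_profile: np.ndarray
    trend_C_per_century: float = 0.0
    trend_start: float = 2000.0
    full_trend_depth_m: float = 100.0
    trend_efold_m: float = 300.0
    layer_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.base_profile = np.asarray(self.base_profile, dtype=float)
        if np.any(self.base_profile < -2.0) or np.any(self.base_profile > 35.0):
            raise ValueError("base temperatures outside [-2, 35] degC")

    def temperature_at(self, year: float) -> np.ndarray:
        """Per-layer temperature (degC) in a given year."""
        dt_years = max(0.0, year - self.trend_start)
        if dt_years == 0.0 or self.trend_C_per_century == 0.0:
            return self.base_profile.copy()
        if self.layer_center is None:
            shape = np.ones_like(self.base_profile)
        else:
            z = np.asarray(self.layer_center, dtype=float)
            shape = np.where(
                z <= self.full_trend_depth_m,
                1.0,
                np.exp(-(z - self.full_trend_depth_m) / self.trend_efold_m),
            )
        warmed = self.base_profile + self.trend_C_per_century * dt_years / 100.0 * shape
        return np.clip(warmed, -2.0, 35.0)


def forcing_table(years, params: MPParameters) -> "pandas.DataFrame":
    """Annual forcing series: waste generation and global MP input."""
    import pandas as pd

    years = np.asarray(years, dtype=int)
    tonnes = waste_generation(years)
    particles = params.F_T * tonnes * PARTICLES_PER_TONNE
    return pd.DataFrame(
        {"year": years, "waste_tonnes_per_yr": tonnes,
         "mp_particles_per_yr": particles}
    )
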