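"""Analysis quantities: export efficiencies, inventories, profile shapes.

Export efficiency is the flux of material past the second model interface
(130 m) divided by the integrated production (for nitrogen) or gross
biological uptake (for microplastic) above that depth, over a common
averaging period (annual by default). A zero numerator over zero
denominator is defined as zero, matching the high-latitude limit where no
MP is taken up at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import ColumnGrid, depth_bracket_inventory
from .transport import RunResult

__all__ = [
    "mp_export_efficiency",
    "pon_export_efficiency",
    "missing_fraction",
    "classify_profile",
    "summarize_run",
    "DEPTH_BRACKETS",
]

#: The depth brackets used for inventory maps: upper ocean, sub-surface,
#: and deep.
DEPTH_BRACKETS = ((0.0, 100.0), (100.0, 500.0), (500.0, None))


def _ratio(flux: float, production: float) -> float:
    if flux < 0 or production < 0:
        raise ValueError("fluxes and production must be non-negative")
    if production == 0.0:
        return 0.0
    return flux / production


def mp_export_efficiency(flux_at_130m: float, integrated_uptake_above: float) -> float:
    """MP export efficiency: export at 130 m over gross uptake above it."""
    return _ratio(flux_at_130m, integrated_uptake_above)


def pon_export_efficiency(detrital_export_at_130m: float,
                          integrated_production_above: float) -> float:
    """PON export efficiency: detrital export at 130 m over production.

    The marine-snow class is referenced to integrated NPP above 130 m, the
    pellet class to integrated grazing. Values above 1 are possible when
    particles are imported from elsewhere.
    """
    return _ratio(detrital_export_at_130m, integrated_production_above)


def missing_fraction(mp_profile, grid: ColumnGrid) -> float:
    """Share of the column MP inventory residing below the surface layer.

    This is the model analogue of the budgetary 'missing' surface MP: the
    fraction of the total stock a surface (top-layer) net would not see.
    Zero total inventory returns 0 by convention.
    """
    mp_profile = np.asarray(mp_profile, dtype=float)
    total = grid.column_integral(mp_profile)
    if total <= 0.0:
        return 0.0
    surface = mp_profile[0] * grid.layer_thickness[0]
    return float(np.clip(1.0 - surface / total, 0.0, 1.0))


@dataclass(frozen=True)
class ProfileShape:
    """Shape classification of a free-MP depth profile."""

    has_local_minimum: bool
    has_subsurface_maximum: bool  # a local max below the (sub)surface minimum
    power_law_r2: float
    is_power_law: bool


def classify_profile(profile, grid: ColumnGrid, r2_threshold: float = 0.95,
                     min_points: int = 4) -> ProfileShape:
    """Classify a free-MP profile: local minima/maxima and power-law tail.

    A surface or sub-surface local minimum followed by a deeper local
    maximum is the signature of the entrainment/release cycle. The
    power-law check is a log-log linear regression on the tail below the
    minimum (or the whole profile when no minimum exists).
    """
    c = np.asarray(profile, dtype=float)
    n = c.size
    min_idx = None
    for i in range(n - 1):
        left_ok = i == 0 or c[i] < c[i - 1]
        if left_ok and c[i] < c[i + 1]:
            min_idx = i
            break
    has_min = min_idx is not None
    has_max = False
    if has_min:
        for j in range(min_idx + 1, n):
            left = c[j] > c[j - 1]
            right = j == n - 1 or c[j] >= c[j + 1]
            if left and right:
                has_max = True
                break

    tail_start = (min_idx + 1) if has_min else 0
    z = grid.layer_center[tail_start:]
    ct = c[tail_start:]
    mask = (ct > 0) & (z > 0)
    r2 = 0.0
    if mask.sum() >= min_points:
        res = stats.linregress(np.log(z[mask]), np.log(ct[mask]))
        r2 = float(res.rvalue**2)
    return ProfileShape(has_local_minimum=has_min, has_subsurface_maximum=has_max,
                        power_law_r2=r2,
                        is_power_law=bool(r2 >= r2_threshold and mask.sum() >= min_points))


def summarize_run(result: RunResult, r2_threshold: float = 0.95) -> pd.DataFrame:
    """Per-year diagnostic records for a column run.

    One tidy row per year: export efficiencies for MP and PON by detritus
    class, depth-bracket inventories of total MP, surface concentration,
    missing fraction, and the profile-shape flags used by the ensemble
    plausibility filter.
    """
    if len(result.years) < 1:
        raise ValueError("run produced no annual output")
    grid = result.grid
    brackets = [(a, b if b is not None else grid.bottom_depth)
                for a, b in DEPTH_BRACKETS]
    rows = []
    sc = result.scalars.set_index("year")
    for i, year in enumerate(result.years):
        row = sc.loc[year]
        total_mp = (result.profiles["MP_free"][i] + result.profiles["MP_A"][i]
                    + result.profiles["MP_Z"][i])
        inv = depth_bracket_inventory(total_mp, grid, brackets)
        shape = classify_profile(result.profiles["MP_free"][i], grid,
                                 r2_threshold=r2_threshold)
        rows.append({
            "year": int(year),
            "mp_a_export_eff": mp_export_efficiency(row["mpa_flux_130"],
                                                    row["a_upt_above"]),
            "mp_z_export_eff": mp_export_efficiency(row["mpz_flux_130"],
                                                    row["p_upt_above"]),
            "mp_export_eff": mp_export_efficiency(
                row["mpa_flux_130"] + row["mpz_flux_130"],
                row["a_upt_above"] + row["p_upt_above"]),
            "pon_a_export_eff": pon_export_efficiency(row["deta_flux_130"],
                                                      row["npp_above"]),
            "pon_z_export_eff": pon_export_efficiency(row["detz_flux_130"],
                                                      row["grazing_above"]),
            "surface_mp_total": row["surface_mp_total"],
            "inventory_total": row["inventory_total"],
            "inv_0_100": inv[0],
            "inv_100_500": inv[1],
            "inv_below_500": inv[2],
            "missing_fraction": missing_fraction(total_mp, grid),
            "has_local_minimum": shape.has_local_minimum,
            "has_subsurface_maximum": shape.has_subsurface_maximum,
            "power_law_r2": shape.power_law_r2,
            "emission_rate": row["emission_rate"],
        })
    return pd.DataFrame(rows)
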