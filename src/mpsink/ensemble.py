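"""Latin-hypercube parameter screening and plausibility filtering.

The seven MP parameters are sampled with a stratified Latin-hypercube
layout: each parameter's range is cut into n equal-probability strata of a
truncated normal centred mid-range (sd = range/4), one draw per stratum,
and the strata are permuted independently per parameter. The marine-snow
uptake half-saturation k_P is optionally split into sub-ranges
(0-1, 1-100, 100-1000 particles/m3) with an equal share of members each,
so the strongly nonlinear low end of the Monod response gets equal
coverage.

Members are screened with six qualitative plausibility criteria
(numerical stability, inventory bounds, pollution-rate and
aggregation-rate bands, 2010 inventory agreement, and profile shape); the
quantitative bands are configuration values with deliberately generous
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .params import MPParameters

__all__ = [
    "HypercubeDesign",
    "FilterThresholds",
    "STAGE_PARAMETERS",
    "sample_hypercube",
    "configure_stage",
    "plausibility_filter",
    "run_ensemble",
]

_PARAM_NAMES = ("F_T", "F_R", "F_A", "k_P", "F_B", "psi_MP", "R_F_MP")

STAGE_PARAMETERS = {
    "no_bio": ("F_T", "F_R"),
    "snow_only": ("F_T", "F_R", "F_A", "k_P", "F_B"),
    "full": _PARAM_NAMES,
}


@dataclass(frozen=True)
class HypercubeDesign:
    """Design of a Latin-hypercube sample over the MP parameter space."""

    n_samples: int = 700
    seed: int = 0
    k_P_strata: tuple[tuple[float, float], ...] = ((0.0, 1.0), (1.0, 100.0),
                                                   (100.0, 1000.0))
    sd_fraction: float = 0.25  # truncated-normal sd as a fraction of the range

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def configure_stage(stage: str) -> tuple[str, ...]:
    """Active parameters for an incremental-complexity stage.

    ``no_bio`` samples only the physical parameters (biological uptake
    off); ``snow_only`` adds marine-snow aggregation; ``full`` adds
    zooplankton grazing (all 7 parameters).
    """
    try:
        return STAGE_PARAMETERS[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; choose from "
                         f"{sorted(STAGE_PARAMETERS)}") from None


def _lhs_column(lo: float, hi: float, n: int, rng: np.random.Generator,
                sd_fraction: float) -> np.ndarray:
    """One LHS margin: one truncated-normal draw per equal-probability stratum."""
    if hi <= lo:
        raise ValueError(f"invalid range ({lo}, {hi})")
    mid = 0.5 * (lo + hi)
    sd = sd_fraction * (hi - lo)
    dist = stats.truncnorm((lo - mid) / sd, (hi - mid) / sd, loc=mid, scale=sd)
    # equal-probability strata in CDF space, one uniform draw within each
    u = (np.arange(n) + rng.random(n)) / n
    values = dist.ppf(u)
    return rng.permutation(values)


def sample_hypercube(design: HypercubeDesign,
                     stage: str = "full") -> list[MPParameters]:
    """Draw a Latin-hypercube sample of MP parameter sets.

    Deterministic given the design seed. Parameters inactive at the given
    stage are fixed at their off values (F_A = 0 and/or psi_MP = 0).
    """
    active = configure_stage(stage)
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    cols: dict[str, np.ndarray] = {}
    for name in _PARAM_NAMES:
        if name not in active:
            continue
        lo, hi = MPParameters.sampling_range(name)
        if name == "k_P" and design.k_P_strata:
            # split members across the k_P sub-ranges, each its own LHS margin
            parts = []
            sizes = [n // len(design.k_P_strata)] * len(design.k_P_strata)
            sizes[0] += n - sum(sizes)
            for (slo, shi), m in zip(design.k_P_strata, sizes):
                if m > 0:
                    parts.append(_lhs_column(slo, shi, m, rng, design.sd_fraction))
            cols[name] = rng.permutation(np.concatenate(parts))
        else:
            cols[name] = _lhs_column(lo, hi, n, rng, design.sd_fraction)

    members = []
    for i in range(n):
        kwargs = {name: float(cols[name][i]) for name in cols}
        if "F_A" not in kwargs:
            kwargs["F_A"] = 0.0
        if "psi_MP" not in kwargs:
            kwargs["psi_MP"] = 0.0
        members.append(MPParameters(**kwargs))
    return members


@dataclass(frozen=True)
class FilterThresholds:
    """Quantitative bands for the plausibility criteria.

    The source statements are qualitative ('roughly', 'generously'), so
    every band here is a configurable package choice; the defaults are
    deliberately wide.
    """

    #: plausible annual ocean-entry fraction: ~4 % estimate with a 10x guard
    max_input_fraction: float = 0.4
    #: generous band on the column-mean MP aggregation rate (particles m^-3 d^-1)
    aggregation_rate_band: tuple[float, float] = (0.0, 1.0e4)
    #: agreement factor around the reference 2010 inventory (either side)
    inventory_agreement_factor: float = 30.0
    #: reference global 2010 MP inventory, particles (independent estimate)
    reference_inventory_particles: float = 51.2e12
    #: ocean area the reference inventory is spread over (m2)
    reference_area_m2: float = 3.6e14
    #: require the entrainment/release profile signature
    require_profile_shape: bool = True


def plausibility_filter(member_metrics: dict, params: MPParameters,
                        thresholds: FilterThresholds | None = None) -> dict:
    """Six boolean plausibility verdicts for one ensemble member.

    ``member_metrics`` must contain: ``stable`` (bool),
    ``inventory_2010`` and ``cumulative_emission_2010`` (particles m^-2),
    ``mean_aggregation_rate`` (particles m^-3 d^-1),
    ``has_subsurface_maximum`` and ``has_local_minimum`` (bool).
    An unstable run fails every criterion.
    """
    t = thresholds or FilterThresholds()
    stable = bool(member_metrics["stable"])
    if not stable:
        verdicts = dict.fromkeys(
            ("stable", "inventory_below_integrated_input", "pollution_rate",
             "aggregation_rate", "inventory_2010", "profile_shape"), False)
        verdicts["plausible"] = False
        return verdicts

    inv = member_metrics["inventory_2010"]
    emis = member_metrics["cumulative_emission_2010"]
    ref_inv = (t.reference_inventory_particles / t.reference_area_m2)
    f = t.inventory_agreement_factor
    agg = member_metrics["mean_aggregation_rate"]
    verdicts = {
        "stable": True,
        "inventory_below_integrated_input": inv <= emis * (1.0 + 1e-9),
        "pollution_rate": params.F_T <= t.max_input_fraction,
        "aggregation_rate": t.aggregation_rate_band[0] <= agg <= t.aggregation_rate_band[1],
        "inventory_2010": (inv == 0.0 and ref_inv == 0.0)
                          or (ref_inv / f <= inv <= ref_inv * f),
        "profile_shape": (not t.require_profile_shape)
                         or (bool(member_metrics["has_subsurface_maximum"])
                             and bool(member_metrics["has_local_minimum"])),
    }
    verdicts["plausible"] = all(verdicts.values())
    return verdicts


def _member_metrics(result, metrics_year: int) -> dict:
    """Summary metrics for the filter from a finished (or failed) run."""
    from .diagnostics import classify_profile

    if not result.stable or len(result.years) == 0:
        return {"stable": False, "inventory_2010": np.nan,
                "cumulative_emission_2010": np.nan,
                "mean_aggregation_rate": np.nan,
                "has_subsurface_maximum": False, "has_local_minimum": False}
    sc = result.scalars
    yr = min(metrics_year, int(result.years[-1]))
    row = sc[sc["year"] == yr].iloc[0]
    i = int(np.nonzero(result.years == yr)[0][0])
    shape = classify_profile(result.profiles["MP_free"][i], result.grid)
    # mean gross aggregation rate per m3 over the upper 130 m
    n_above = max(1, int(np.searchsorted(result.grid.interface_depth, 130.0 + 1e-6)))
    mean_agg = row["a_upt_above"] / float(result.grid.layer_thickness[:n_above].sum())
    upto = sc[sc["year"] <= yr]
    emis_cum = float((upto["emission_rate"] * 365.0).sum())
    return {"stable": True,
            "inventory_2010": float(row["inventory_total"]),
            "cumulative_emission_2010": emis_cum,
            "mean_aggregation_rate": float(mean_agg),
            "has_subsurface_maximum": shape.has_subsurface_maximum,
            "has_local_minimum": shape.has_local_minimum}


def run_ensemble(design: HypercubeDesign, stage: str = "full",
                 base_config=None, thresholds: FilterThresholds | None = None,
                 end_year: int = 2010, metrics_year: int = 2010) -> pd.DataFrame:
    """Execute every hypercube member and collect verdicts and metrics.

    ``base_config`` is a :class:`~mpsink.config.RunConfig` whose MP
    parameters are replaced member by member (defaults to a desk-scale
    tropical column). Returns one row per member; a member that raises is
    recorded as unstable and the ensemble continues. Fully reproducible
    given the design seed.
    """
    from .config import RunConfig

    cfg = base_config if base_config is not None else RunConfig()
    members = sample_hypercube(design, stage=stage)
    rows = []
    for i, params in enumerate(members):
        member_cfg = replace(cfg, params=params, end_year=end_year)
        try:
            result = member_cfg.build_simulation().run(
                start_year=cfg.start_year, end_year=end_year,
                spinup_years=cfg.spinup_years)
            metrics = _member_metrics(result, metrics_year)
        except Exception as exc:  # member failure is data, not a crash
            metrics = {"stable": False, "inventory_2010": np.nan,
                       "cumulative_emission_2010": np.nan,
                       "mean_aggregation_rate": np.nan,
                       "has_subsurface_maximum": False,
                       "has_local_minimum": False}
        verdicts = plausibility_filter(metrics, params, thresholds)
        row = {"member": i}
        row.update({name: getattr(params, name) for name in _PARAM_NAMES})
        row.update(metrics)
        row.update(verdicts)
        rows.append(row)
    return pd.DataFrame(rows)
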