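"""Run configuration: YAML parsing, validation, and simulation assembly.

A run is described by a YAML file (all keys optional; an empty file means
all defaults, a single global-mean tropical column):

.. code-block:: yaml

    fixture: test_med          # or an explicit params: block
    grid:
      thicknesses_m: [50, 80, ...]   # or n_layers/bottom_depth_m
      cell_area_m2: 3.6e14
    scenario:
      surface_C: 28.0
      deep_C: 2.0
      warming_C_per_century: 0.0
    forcing:
      start_year: 1950
      base_tonnes: 2.0e6
      growth_rate: 0.084
    years: {start: 1950, end: 2020}
    spinup_years: 20
    dt_days: 0.5
    emission_weight: 1.0
    ecosystem: {mu_D0: 0.032, ...}
    transport: {w_D0: 14.0, ...}
    seed: 0

Unknown keys are rejected with an error listing them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ecosystem import EcoParams
from .forcing import BASE_TONNES, GROWTH_RATE, START_YEAR, TemperatureScenario, temperature_profile
from .grid import GLOBAL_OCEAN_AREA_M2, ColumnGrid, build_grid, default_grid
from .params import FIXTURES, MPParameters, fixture
from .transport import Simulation, TransportConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one column run."""

    params: MPParameters = field(default_factory=lambda: fixture("test_med"))
    fixture_name: str | None = "test_med"
    grid_thicknesses: tuple[float, ...] | None = None
    n_layers: int = 19
    bottom_depth_m: float = 5000.0
    cell_area_m2: float = GLOBAL_OCEAN_AREA_M2
    surface_C: float = 28.0
    deep_C: float = 2.0
    warming_C_per_century: float = 0.0
    forcing_base_tonnes: float = BASE_TONNES
    forcing_growth_rate: float = GROWTH_RATE
    forcing_start_year: int = START_YEAR
    start_year: int = 1950
    end_year: int = 2020
    spinup_years: int = 20
    dt_days: float = 0.5
    emission_weight: float = 1.0
    eco_overrides: tuple[tuple[str, float], ...] = ()
    transport_overrides: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def build_grid(self) -> ColumnGrid:
        if self.grid_thicknesses is not None:
            return build_grid(list(self.grid_thicknesses),
                              cell_area=self.cell_area_m2)
        return default_grid(n_layers=self.n_layers,
                            bottom_depth=self.bottom_depth_m,
                            cell_area=self.cell_area_m2)

    def build_eco_params(self) -> EcoParams:
        return EcoParams(**dict(self.eco_overrides))

    def build_transport(self) -> TransportConfig:
        kwargs = dict(self.transport_overrides)
        kwargs.setdefault("dt", self.dt_days)
        return TransportConfig(**kwargs)

    def build_scenario(self, grid: ColumnGrid | None = None) -> TemperatureScenario:
        grid = grid or self.build_grid()
        base = temperature_profile(grid, self.surface_C, deep_C=self.deep_C)
        return TemperatureScenario(base_profile=base,
                                   trend_C_per_century=self.warming_C_per_century,
                                   layer_center=grid.layer_center)

    def build_simulation(self) -> Simulation:
        grid = self.build_grid()
        return Simulation(grid=grid, mp_params=self.params,
                          scenario=self.build_scenario(grid),
                          eco_params=self.build_eco_params(),
                          transport=self.build_transport(),
                          emission_weight=self.emission_weight,
                          forcing_base_tonnes=self.forcing_base_tonnes,
                          forcing_growth_rate=self.forcing_growth_rate,
                          forcing_start_year=self.forcing_start_year)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = {k: getattr(self.params, k)
                       for k in ("F_T", "F_R", "F_A", "k_P", "F_B",
                                 "psi_MP", "R_F_MP")}
        return d


_TOP_KEYS = {"fixture", "params", "grid", "scenario", "forcing", "years",
             "spinup_years", "dt_days", "emission_weight", "ecosystem",
             "transport", "seed"}
_GRID_KEYS = {"thicknesses_m", "n_layers", "bottom_depth_m", "cell_area_m2"}
_SCEN_KEYS = {"surface_C", "deep_C", "warming_C_per_century"}
_FORC_KEYS = {"start_year", "base_tonnes", "growth_rate"}
_PARAM_KEYS = {"F_T", "F_R", "F_A", "k_P", "F_B", "psi_MP", "R_F_MP"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    A missing file raises a clear error; an empty file yields the
    all-defaults configuration.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")

    kwargs: dict = {}
    fixture_name = raw.get("fixture")
    if fixture_name is not None and "params" in raw:
        raise ConfigError("give either 'fixture' or 'params', not both")
    if fixture_name is not None:
        kwargs["params"] = fixture(fixture_name)
        kwargs["fixture_name"] = fixture_name
    elif "params" in raw:
        _check_keys(raw["params"], _PARAM_KEYS, "params")
        kwargs["params"] = MPParameters(**raw["params"])
        kwargs["fixture_name"] = None

    if "grid" in raw:
        g = raw["grid"]
        _check_keys(g, _GRID_KEYS, "grid")
        if "thicknesses_m" in g:
            kwargs["grid_thicknesses"] = tuple(float(t) for t in g["thicknesses_m"])
        if "n_layers" in g:
            kwargs["n_layers"] = int(g["n_layers"])
        if "bottom_depth_m" in g:
            kwargs["bottom_depth_m"] = float(g["bottom_depth_m"])
        if "cell_area_m2" in g:
            kwargs["cell_area_m2"] = float(g["cell_area_m2"])
    if "scenario" in raw:
        s = raw["scenario"]
        _check_keys(s, _SCEN_KEYS, "scenario")
        for key in _SCEN_KEYS & set(s):
            kwargs[key if key != "surface_C" else "surface_C"] = float(s[key])
    if "forcing" in raw:
        f = raw["forcing"]
        _check_keys(f, _FORC_KEYS, "forcing")
        if "start_year" in f:
            kwargs["forcing_start_year"] = int(f["start_year"])
        if "base_tonnes" in f:
            kwargs["forcing_base_tonnes"] = float(f["base_tonnes"])
        if "growth_rate" in f:
            kwargs["forcing_growth_rate"] = float(f["growth_rate"])
    if "years" in raw:
        y = raw["years"]
        _check_keys(y, {"start", "end"}, "years")
        if "start" in y:
            kwargs["start_year"] = int(y["start"])
        if "end" in y:
            kwargs["end_year"] = int(y["end"])
    for key, cast in (("spinup_years", int), ("dt_days", float),
                      ("emission_weight", float), ("seed", int)):
        if key in raw:
            kwargs[key] = cast(raw[key])
    if "ecosystem" in raw:
        allowed = {f.name for f in dataclasses.fields(EcoParams)}
        _check_keys(raw["ecosystem"], allowed, "ecosystem")
        kwargs["eco_overrides"] = tuple(sorted(
            (k, float(v)) for k, v in raw["ecosystem"].items()))
    if "transport" in raw:
        allowed = {f.name for f in dataclasses.fields(TransportConfig)}
        _check_keys(raw["transport"], allowed, "transport")
        kwargs["transport_overrides"] = tuple(sorted(
            (k, float(v)) for k, v in raw["transport"].items()))
    return RunConfig(**kwargs)
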