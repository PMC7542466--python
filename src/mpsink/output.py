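"""Output writers: NetCDF (scipy engine) and tidy CSV.

NetCDF is the primary format for gridded model output; the conservation
ledger and the resolved configuration travel as global attributes. The
CSV writer produces one row per (year, layer) for desk inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .transport import RunResult

__all__ = ["write_netcdf", "write_csv", "read_netcdf", "tidy_frame"]


def write_netcdf(result: RunResult, path, config_dict: dict | None = None,
                 seed: int | None = None) -> Path:
    """Write a run to NetCDF (NETCDF3_64BIT via the scipy engine)."""
    if len(result.years) == 0:
        raise ValueError("run produced no output to write")
    ds = result.to_dataset()
    if config_dict is not None:
        ds.attrs["config_json"] = json.dumps(config_dict)
        if config_dict.get("fixture_name"):
            ds.attrs["fixture"] = config_dict["fixture_name"]
    if seed is not None:
        ds.attrs["seed"] = int(seed)
    path = Path(path)
    ds.attrs["stable"] = int(result.stable)
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")
    return path


def read_netcdf(path) -> "xarray.Dataset":
    import xarray as xr

    return xr.open_dataset(path, engine="scipy")


def tidy_frame(result: RunResult) -> pd.DataFrame:
    """Long-format frame: one row per (year, layer) with every tracer."""
    if len(result.years) == 0:
        raise ValueError("run produced no output")
    n_y = len(result.years)
    n_l = result.grid.n_layers
    rows = {
        "year": np.repeat(result.years, n_l),
        "layer": np.tile(np.arange(n_l), n_y),
        "depth_m": np.tile(result.grid.layer_center, n_y),
    }
    for name, arr in result.profiles.items():
        rows[name] = arr.reshape(-1)
    return pd.DataFrame(rows)


def write_csv(result: RunResult, path) -> Path:
    path = Path(path)
    tidy_frame(result).to_csv(path, index=False, float_format="%.10g")
    return path
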