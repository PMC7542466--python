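"""Vertical column grid and depth-integration utilities.

The model runs on independent one-dimensional water columns. The nominal
grid mimics a coarse-resolution ocean model: a 50 m surface layer, an 80 m
second layer (so the second interface sits at 130 m, the depth at which
export is diagnosed), and geometrically widening layers down to an abyssal
bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["ColumnGrid", "build_grid", "default_grid", "depth_bracket_inventory"]

#: Horizontal area a single column stands in for when it represents the
#: global surface ocean (m^2).  Used by single-column emission scaling.
GLOBAL_OCEAN_AREA_M2 = 3.6e14


@dataclass(frozen=True)
class ColumnGrid:
    """Geometry of one vertical column.

    Parameters
    ----------
    layer_thickness : ndarray of float
        Thickness of each layer in metres, surface first.
    cell_area : float
        Nominal horizontal area of the column (m^2). A single column run
        uses this to convert absolute emission rates (particles/yr) into
        concentrations; the default 1 m^2 makes inventories per-area.
    """

    layer_thickness: np.ndarray
    cell_area: float = 1.0
    interface_depth: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        thick = np.asarray(self.layer_thickness, dtype=float)
        if thick.ndim != 1 or thick.size == 0:
            raise ValueError("layer_thickness must be a non-empty 1-D sequence")
        if np.any(thick <= 0):
            raise ValueError("all layer thicknesses must be positive")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        object.__setattr__(self, "layer_thickness", thick)
        object.__setattr__(self, "interface_depth", np.cumsum(thick))

    @property
    def n_layers(self) -> int:
        return self.layer_thickness.size

    @property
    def bottom_depth(self) -> float:
        return float(self.interface_depth[-1])

    @property
    def layer_center(self) -> np.ndarray:
        top = np.concatenate([[0.0], self.interface_depth[:-1]])
        return 0.5 * (top + self.interface_depth)

    @property
    def layer_top(self) -> np.ndarray:
        return np.concatenate([[0.0], self.interface_depth[:-1]])

    def column_integral(self, field_values: np.ndarray) -> float:
        """Depth integral of a per-layer concentration (units * m)."""
        field_values = np.asarray(field_values, dtype=float)
        if field_values.shape != self.layer_thickness.shape:
            raise ValueError("field shape does not match grid")
        return float(np.sum(field_values * self.layer_thickness))


def build_grid(thicknesses, cell_area: float = 1.0) -> ColumnGrid:
    """Build a :class:`ColumnGrid` from layer thicknesses (m, surface first)."""
    return ColumnGrid(np.asarray(thicknesses, dtype=float), cell_area=cell_area)


def default_grid(
    n_layers: int = 19,
    bottom_depth: float = 5000.0,
    cell_area: float = 1.0,
) -> ColumnGrid:
    """The nominal 19-layer grid: 50 m, 80 m, then geometric to the bottom.

    Layers 3..n widen geometrically starting from the 80 m second layer so
    that the interfaces reach ``bottom_depth`` exactly. The exact deep
    spacing is a modelling choice; only the 50 m surface layer and the
    130 m second interface are structural.
    """
    if n_layers < 3:
        raise ValueError("default grid needs at least 3 layers")
    n_deep = n_layers - 2
    remaining = bottom_depth - 130.0
    if remaining <= 0:
        raise ValueError("bottom_depth must exceed 130 m for the default grid")
    t0 = 80.0  # deep layers continue geometrically from the 80 m second layer

    def gap(r: float) -> float:
        # sum of t0*r, t0*r^2, ..., t0*r^n_deep minus the remaining depth
        return t0 * r * (r**n_deep - 1.0) / (r - 1.0) - remaining

    if abs(gap(1.0 + 1e-12)) < 1e-6:
        ratio = 1.0
        deep = np.full(n_deep, remaining / n_deep)
    else:
        ratio = brentq(gap, 1.0 + 1e-9, 2.0)
        deep = t0 * ratio ** np.arange(1, n_deep + 1)
        deep *= remaining / deep.sum()  # absorb the last ulp of rounding
    return build_grid(np.concatenate([[50.0, 80.0], deep]), cell_area=cell_area)


def depth_bracket_inventory(field_values, grid: ColumnGrid, brackets) -> np.ndarray:
    """Areal inventory of a per-layer concentration over depth brackets.

    Bracket edges may split a layer; the layer's contribution is pro-rated
    linearly by the overlapped thickness fraction. Returns one value per
    bracket in ``units * m`` (e.g. particles m^-2 for particles m^-3 input).
    """
    field_values = np.asarray(field_values, dtype=float)
    if field_values.shape != grid.layer_thickness.shape:
        raise ValueError("field shape does not match grid")
    tops = grid.layer_top
    bots = grid.interface_depth
    out = np.empty(len(brackets), dtype=float)
    for j, (z_top, z_bot) in enumerate(brackets):
        if z_top >= z_bot:
            raise ValueError(f"inverted bracket ({z_top}, {z_bot})")
        if z_top < 0 or z_bot > grid.bottom_depth + 1e-9:
            raise ValueError(
                f"bracket ({z_top}, {z_bot}) outside [0, {grid.bottom_depth}]"
            )
        overlap = np.clip(np.minimum(bots, z_bot) - np.maximum(tops, z_top), 0.0, None)
        out[j] = float(np.sum(field_values * overlap))
    return out
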