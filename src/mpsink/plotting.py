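"""Minimal quick-look plots for column runs."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_profiles", "plot_timeseries"]


def plot_profiles(result, year=None, ax=None):
    """Depth profiles of the three MP pools for one year (default: last)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    i = -1 if year is None else int(np.nonzero(result.years == year)[0][0])
    z = result.grid.layer_center
    for name, style in (("MP_free", "-"), ("MP_A", "--"), ("MP_Z", ":")):
        ax.plot(result.profiles[name][i], z, style, label=name)
    ax.invert_yaxis()
    ax.set_xlabel("particles m$^{-3}$")
    ax.set_ylabel("depth (m)")
    ax.legend()
    ax.set_title(f"year {result.years[i]}")
    return ax


def plot_timeseries(result, ax=None):
    """Surface total MP concentration through time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.years, result.scalars["surface_mp_total"])
    ax.set_xlabel("year")
    ax.set_ylabel("surface MP (particles m$^{-3}$)")
    return ax
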