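"""Optional diagnostic plots (matplotlib).

Mirrors the standard validation graphics: RMSE vs hidden-layer size, binned
error statistics, daily global metric time series, spatial bias maps, and the
input-sensitivity bar chart.  Every function takes an ``ax`` keyword so plots
compose into panels; figures are returned, never shown.
"""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_hidden_sweep(sweep, ax=None):
    """Test RMSE as a function of hidden-layer size."""
    ax = _ax(ax)
    ax.plot(sweep.k_values, sweep.test_rmse, "o-")
    ax.axvline(sweep.best_k, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("hidden neurons k")
    ax.set_ylabel("test RMSE (mg/m$^3$)")
    return ax


def plot_binned(bs, kind="bias", ax=None):
    """Binned bias (or RMSE) vs observed Chl-a with residual-std bars."""
    ax = _ax(ax)
    t = bs.table[~bs.table["overflow"]]
    centers = 0.5 * (t["bin_lo"] + t["bin_hi"])
    ax.errorbar(centers, t[kind], yerr=t["resid_std"], fmt="o-", capsize=2)
    ax.axhline(0.0, color="k", lw=0.6)
    ax.set_xlabel("observed Chl-a (mg/m$^3$)")
    ax.set_ylabel(f"{kind} (mg/m$^3$)")
    return ax


def plot_metric_series(series, metric="rmse", ax=None, **kwargs):
    """Daily global metric time series (one line per call; overlay variants)."""
    ax = _ax(ax)
    ax.plot(series.index, series[metric], **kwargs)
    ax.set_xlabel("day")
    ax.set_ylabel(metric)
    if kwargs.get("label"):
        ax.legend()
    return ax


def plot_bias_map(bias_field, lat, lon, ax=None, vmax=None):
    """Spatial map of the time-mean bias (obs - pred)."""
    ax = _ax(ax)
    vmax = vmax or np.nanmax(np.abs(bias_field))
    im = ax.pcolormesh(lon, lat, bias_field, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.figure.colorbar(im, ax=ax, label="bias (mg/m$^3$)")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax


def plot_sensitivity(report, ax=None):
    """Bar chart of the ensemble-averaged |Jacobian| per input."""
    ax = _ax(ax)
    idx = np.arange(1, len(report.values) + 1)
    ax.bar(idx, report.values)
    ax.set_xticks(idx, report.names, rotation=90, fontsize=7)
    unit = "mg/m$^3$ per unit" if report.physical_units else "standardized"
    ax.set_ylabel(f"mean |dChl-a/dx| ({unit})")
    return ax
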