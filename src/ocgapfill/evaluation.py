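"""Validation diagnostics: bias/RMSE/correlation, binned errors, time series,
spatial bias maps, the hidden-size sweep, and the uncertainty decomposition.

Sign convention: bias = mean(observed - predicted), i.e. a positive bias means
the network underestimates the observations.  The total error of a trained
network splits as RMSE = eps_app + eps, where eps_app is the approximation
error of the network itself — estimated by training a one-input network to
emulate the identity mapping on the target variable — and eps is the residual
uncertainty from subgrid variability and observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import fit_standardizer
from .mlp import Architecture, TrainingHistory, TrainingOptions, train_mlp

__all__ = [
    "Metrics",
    "BinnedStats",
    "UncertaintyDecomposition",
    "SweepResult",
    "compute_metrics",
    "filter_threshold",
    "binned_stats",
    "daily_metric_series",
    "spatial_bias_map",
    "hidden_size_sweep",
    "estimate_epsilon_app",
    "decompose_rmse",
]

#: observed-Chl-a threshold above which records are dropped in filtered stats
DEFAULT_CHLA_THRESHOLD = 1.0  # mg/m^3


@dataclass
class Metrics:
    """bias = mean(obs - pred); cc is NaN when either series is constant."""

    bias: float
    rmse: float
    cc: float
    n: int


def compute_metrics(pred: np.ndarray, obs: np.ndarray, weights=None) -> Metrics:
    """Bias, RMSE and Pearson correlation of predictions against observations.

    ``weights`` (optional, nonnegative) turn all three statistics into their
    weighted counterparts — used for cos(latitude) area weighting of global
    means, which is off by default.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs obs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty inputs")
    if weights is None:
        w = np.ones_like(obs)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != obs.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be nonnegative, same length, not all zero")
    w = w / w.sum()
    resid = obs - pred
    bias = float(w @ resid)
    rmse = float(np.sqrt(w @ resid**2))
    dp = pred - w @ pred
    do = obs - w @ obs
    vp, vo = w @ dp**2, w @ do**2
    if pred.size < 2 or vp == 0.0 or vo == 0.0:
        cc = float("nan")
    else:
        cc = float((w @ (dp * do)) / np.sqrt(vp * vo))
    return Metrics(bias=bias, rmse=rmse, cc=cc, n=int(pred.size))


def filter_threshold(
    records: pd.DataFrame,
    max_chla: float = DEFAULT_CHLA_THRESHOLD,
    column: str = "chla",
) -> pd.DataFrame:
    """Keep records with observed Chl-a <= ``max_chla`` (boundary inclusive).

    The few records above 1 mg/m^3 (coastal, high-noise regimes; about 0.2%
    of typical data) dominate the error statistics, so filtered variants of
    every diagnostic are reported alongside the full-data ones.
    """
    return records[records[column] <= max_chla]


@dataclass
class BinnedStats:
    """Per-bin error statistics binned by OBSERVED Chl-a.

    Bins are half-open ``[lo, hi)`` with the last bin closed; records outside
    the edge range are collected in an ``overflow`` row so counts always sum
    to N and fractions to 1.
    """

    table: pd.DataFrame  # rows: one per bin (+ optional overflow)
    edges: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy()


def binned_stats(pred, obs, edges) -> BinnedStats:
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and nonempty")
    nbins = len(edges) - 1
    # np.digitize with right=False gives [lo, hi); fold the exact top edge
    # into the last bin so it is closed.
    idx = np.digitize(obs, edges) - 1
    idx[obs == edges[-1]] = nbins - 1
    in_range = (idx >= 0) & (idx < nbins)
    n_total = obs.size
    rows = []
    resid = obs - pred
    for b in range(nbins):
        sel = in_range & (idx == b)
        cnt = int(sel.sum())
        row = {
            "bin_lo": edges[b],
            "bin_hi": edges[b + 1],
            "count": cnt,
            "fraction": cnt / n_total,
        }
        if cnt:
            m = compute_metrics(pred[sel], obs[sel])
            row.update(
                bias=m.bias,
                rmse=m.rmse,
                cc=m.cc,
                resid_std=float(np.std(resid[sel])),
                mean_pred=float(pred[sel].mean()),
                mean_obs=float(obs[sel].mean()),
            )
        else:
            row.update(bias=np.nan, rmse=np.nan, cc=np.nan, resid_std=np.nan,
                       mean_pred=np.nan, mean_obs=np.nan)
        rows.append(row)
    n_over = int((~in_range).sum())
    if n_over:
        sel = ~in_range
        m = compute_metrics(pred[sel], obs[sel])
        rows.append(
            {
                "bin_lo": np.nan,
                "bin_hi": np.nan,
                "count": n_over,
                "fraction": n_over / n_total,
                "bias": m.bias,
                "rmse": m.rmse,
                "cc": m.cc,
                "resid_std": float(np.std(resid[sel])),
                "mean_pred": float(pred[sel].mean()),
                "mean_obs": float(obs[sel].mean()),
            }
        )
    table = pd.DataFrame(rows)
    table["overflow"] = False
    if n_over:
        table.loc[table.index[-1], "overflow"] = True
    return BinnedStats(table=table, edges=edges)


def daily_metric_series(
    records: pd.DataFrame,
    apply_filter: bool = False,
    threshold: float = DEFAULT_CHLA_THRESHOLD,
    obs_column: str = "chla",
    pred_column: str = "pred",
    time_column: str = "time",
    area_weighted: bool = False,
    lat_column: str = "lat",
) -> pd.DataFrame:
    """Global bias/RMSE/CC per day.

    Global means are unweighted over valid grid points by default;
    ``area_weighted=True`` applies cos(latitude) weights instead.  Days
    present in ``records`` but with no valid (or no surviving, when filtered)
    points get a NaN row so the series keeps one entry per day.
    """
    days = np.unique(records[time_column].to_numpy())
    work = records.dropna(subset=[obs_column, pred_column])
    if apply_filter:
        work = filter_threshold(work, threshold, column=obs_column)
    rows = []
    grouped = dict(iter(work.groupby(time_column)))
    for day in days:
        g = grouped.get(day)
        if g is None or len(g) == 0:
            rows.append({"time": day, "bias": np.nan, "rmse": np.nan, "cc": np.nan, "n": 0})
            continue
        weights = (
            np.cos(np.deg2rad(g[lat_column].to_numpy())) if area_weighted else None
        )
        m = compute_metrics(
            g[pred_column].to_numpy(), g[obs_column].to_numpy(), weights=weights
        )
        rows.append({"time": day, "bias": m.bias, "rmse": m.rmse, "cc": m.cc, "n": m.n})
    return pd.DataFrame(rows).set_index("time")


def spatial_bias_map(
    obs: np.ndarray,
    pred: np.ndarray,
    apply_filter: bool = False,
    threshold: float = DEFAULT_CHLA_THRESHOLD,
):
    """Per-cell time-mean of (obs - pred) over valid days.

    ``obs`` and ``pred`` are (time, lat, lon) arrays with NaN marking invalid
    points; cells with no valid data anywhere stay NaN in the output.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 3:
        raise ValueError("obs and pred must be equal-shaped (time, lat, lon) arrays")
    resid = obs - pred
    if apply_filter:
        resid = np.where(obs <= threshold, resid, np.nan)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        return np.nanmean(resid, axis=0)


# ---------------------------------------------------------------------------
# hidden-size sweep

@dataclass
class SweepResult:
    """Test RMSE per hidden-layer size; ties break toward the smaller k."""

    k_values: list[int]
    test_rmse: list[float]
    best_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "test_rmse": self.test_rmse})


def hidden_size_sweep(
    x_train, y_train, x_test, y_test,
    k_values,
    seed: int = 0,
    opts: TrainingOptions | None = None,
) -> SweepResult:
    """Train one network per candidate hidden size and report test RMSE.

    Past the size where the mapping is captured, extra hidden units start
    fitting the noise; the minimizing k is reported, with ties broken toward
    the smaller (more parsimonious) network.
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be nonempty")
    opts = opts or TrainingOptions()
    x_train = np.atleast_2d(np.asarray(x_train, dtype=float))
    rmses = []
    for k in k_values:
        arch = Architecture(x_train.shape[1], int(k), 1)
        _, hist = train_mlp(x_train, y_train, x_test, y_test, arch, replace(opts, seed=seed))
        rmses.append(hist.final_test_rmse)
    best_idx = min(range(len(k_values)), key=lambda i: (rmses[i], k_values[i]))
    return SweepResult(k_values=k_values, test_rmse=rmses, best_k=int(k_values[best_idx]))


# ---------------------------------------------------------------------------
# uncertainty decomposition via the identity-mapping network

@dataclass
class UncertaintyDecomposition:
    """Split of total RMSE into approximation error and residual uncertainty."""

    rmse: float
    eps_app: float
    eps: float

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.eps_app < 0 or self.eps < 0:
            raise ValueError("all decomposition components must be >= 0")


def decompose_rmse(total_rmse: float, eps_app: float) -> UncertaintyDecomposition:
    """RMSE = eps_app + eps; eps_app is capped at the total so eps >= 0."""
    eps_app = min(eps_app, total_rmse)
    return UncertaintyDecomposition(rmse=total_rmse, eps_app=eps_app, eps=total_rmse - eps_app)


def estimate_epsilon_app(
    values: np.ndarray,
    k: int = 30,
    seed: int = 0,
    opts: TrainingOptions | None = None,
) -> tuple[float, Metrics, TrainingHistory]:
    """Approximation-error floor from an identity-emulating 1:k:1 network.

    A network with the target variable as its only input is trained to
    reproduce that same variable (the identity mapping) on an alternating
    even/odd split of ``values``.  Its test RMSE is the part of any full
    model's error attributable to the network approximation itself, not to
    the data.  Returns ``(eps_app, test_metrics, history)`` with eps_app in
    the physical units of ``values``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 1000:
        raise ValueError("need at least 1000 target values")
    if np.std(values) == 0.0:
        raise ValueError("degenerate constant targets")
    opts = opts or TrainingOptions(max_epochs=600, patience=100, seed=seed)
    std = fit_standardizer(values[:, None], values)
    xs = std.transform_x(values[:, None])
    ys = std.transform_y(values)
    x_train, y_train = xs[0::2], ys[0::2]
    x_test, y_test = xs[1::2], ys[1::2]
    arch = Architecture(1, int(k), 1)
    params, hist = train_mlp(x_train, y_train, x_test, y_test, arch, replace(opts, seed=seed))
    from .mlp import mlp_forward

    pred = std.inverse_y(mlp_forward(params, x_test)[:, 0])
    obs = std.inverse_y(y_test)
    m = compute_metrics(pred, obs)
    return m.rmse, m, hist
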