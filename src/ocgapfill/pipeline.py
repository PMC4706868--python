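"""End-to-end orchestration: records from grids, the train/test partition,
ensemble training, and gap filling of chlorophyll fields.

The partitioning mirrors the operational recipe: flatten the gridded data to
a canonical record stream (time-major, then latitude, then longitude) and
send every second complete record to training, the rest to testing; held-out
whole years serve for validation and generalization experiments.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import Ensemble, ensemble_predict, train_ensemble
from .features import (
    INPUT_NAMES,
    PREDICTOR_NAMES,
    TARGET_NAME,
    Standardizer,
    encode_frame,
    fit_standardizer,
)
from .gridded import PROVENANCE, GriddedDataset
from .mlp import Architecture, TrainingOptions
from .evaluation import compute_metrics, daily_metric_series

__all__ = [
    "SplitSpec",
    "ExperimentConfig",
    "assemble_records",
    "alternating_split",
    "prepare_training",
    "train_gapfill_ensemble",
    "predict_records",
    "fill_gaps",
    "generalization_experiment",
]

log = logging.getLogger("ocgapfill")


@dataclass
class SplitSpec:
    """How to partition records: alternating records (default) or by year."""

    mode: str = "alternating"  # "alternating" | "by-year"
    train_years: list[int] | None = None
    validation_years: list[int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("alternating", "by-year"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "by-year" and not self.train_years:
            raise ValueError("by-year split requires train_years")


def assemble_records(g: GriddedDataset) -> pd.DataFrame:
    """One record per (cell, day) with all 17 physical predictors valid.

    Records are emitted in canonical order (time-major, then lat, then lon).
    Rows whose chlorophyll is missing are kept with NaN target — these are
    the gaps to fill.  Rows missing any predictor are dropped (they are
    unusable for either training or prediction); their count per variable is
    attached as ``df.attrs["missingness"]``.
    """
    df = g.to_frame()
    ocean = df["land"] == 0 if "land" in df.columns else pd.Series(True, index=df.index)
    df = df[ocean]
    complete = np.ones(len(df), dtype=bool)
    missingness = {}
    for name in PREDICTOR_NAMES:
        valid = np.isfinite(df[name].to_numpy())
        missingness[name] = int((~valid).sum())
        complete &= valid
    out = df[complete].copy()
    out = out.rename(columns={"chlor_a": TARGET_NAME})
    if len(out) == 0:
        raise ValueError(
            f"no complete-predictor records; per-variable missing counts: {missingness}"
        )
    out.attrs["missingness"] = missingness
    out.attrs["n_excluded"] = int((~complete).sum())
    return out.reset_index(drop=True)


def alternating_split(
    records: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split labelled records: even canonical indices train, odd test.

    Records must already be in canonical order (as :func:`assemble_records`
    yields them).  With ``mode="by-year"`` the alternation is applied within
    the training years only.
    """
    spec = spec or SplitSpec()
    labelled = records[np.isfinite(records[TARGET_NAME].to_numpy())]
    if spec.mode == "by-year":
        labelled = labelled[labelled["year"].isin(spec.train_years)]
    if len(labelled) < 2:
        raise ValueError("need at least 2 labelled records to split")
    train = labelled.iloc[0::2]
    test = labelled.iloc[1::2]
    return train, test


def prepare_training(
    train: pd.DataFrame,
    test: pd.DataFrame,
    day_denominator: int = 366,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, Standardizer]:
    """Encode and z-score train/test records; constants come from train only."""
    enc_train = encode_frame(train, day_denominator)
    enc_test = encode_frame(test, day_denominator)
    x_train = enc_train[INPUT_NAMES].to_numpy()
    x_test = enc_test[INPUT_NAMES].to_numpy()
    y_train = enc_train[TARGET_NAME].to_numpy()
    y_test = enc_test[TARGET_NAME].to_numpy()
    std = fit_standardizer(x_train, y_train)
    return (
        std.transform_x(x_train),
        std.transform_y(y_train),
        std.transform_x(x_test),
        std.transform_y(y_test),
        std,
    )


def train_gapfill_ensemble(
    records: pd.DataFrame,
    arch: Architecture | None = None,
    n_members: int = 6,
    base_seed: int = 0,
    opts: TrainingOptions | None = None,
    split: SplitSpec | None = None,
    day_denominator: int = 366,
) -> Ensemble:
    """Alternating split -> standardize -> train the ensemble."""
    t0 = _time.perf_counter()
    train, test = alternating_split(records, split)
    xs_tr, ys_tr, xs_te, ys_te, std = prepare_training(train, test, day_denominator)
    arch = arch or Architecture(len(INPUT_NAMES), 30, 1)
    log.info(
        "training ensemble %s x%d on %d train / %d test records",
        arch, n_members, len(train), len(test),
    )
    ens = train_ensemble(
        xs_tr, ys_tr, xs_te, ys_te, arch,
        n_members=n_members, base_seed=base_seed, opts=opts, standardizer=std,
    )
    log.info("ensemble trained in %.1f s", _time.perf_counter() - t0)
    return ens


def predict_records(
    e: Ensemble, records: pd.DataFrame, day_denominator: int = 366
) -> np.ndarray:
    """Ensemble-mean chlorophyll (mg/m^3) for each record."""
    if e.standardizer is None:
        raise ValueError("ensemble has no standardizer attached")
    enc = encode_frame(records, day_denominator)
    xs = e.standardizer.transform_x(enc[INPUT_NAMES].to_numpy())
    mean, _ = ensemble_predict(e, xs)
    return np.asarray(mean).reshape(len(records))


def fill_gaps(
    e: Ensemble, g: GriddedDataset, day_denominator: int = 366
) -> GriddedDataset:
    """Produce the gap-filled chlorophyll field with a provenance flag.

    Observed values are never overwritten: the filled field equals the
    observation wherever one exists, the ensemble mean wherever predictors
    are complete but the observation is missing, and stays missing (flagged
    unfillable) where any predictor is missing too.
    """
    if e.arch.n_inputs != len(INPUT_NAMES):
        raise ValueError(
            f"ensemble expects {e.arch.n_inputs} inputs, encoder produces {len(INPUT_NAMES)}"
        )
    t0 = _time.perf_counter()
    records = assemble_records(g)
    pred = predict_records(e, records, day_denominator)

    T, I, J = g.shape
    obs = g.data["chlor_a"].to_numpy()
    filled = obs.copy()
    provenance = np.full((T, I, J), PROVENANCE["unfillable"], dtype=np.int8)
    provenance[:, ~g.ocean_mask] = PROVENANCE["land"]
    provenance[np.isfinite(obs)] = PROVENANCE["observed"]

    ti = np.searchsorted(g.time, records["time"].to_numpy())
    ii = np.searchsorted(g.lat, records["lat"].to_numpy())
    jj = np.searchsorted(g.lon, records["lon"].to_numpy())
    gap = ~np.isfinite(obs[ti, ii, jj])
    filled[ti[gap], ii[gap], jj[gap]] = pred[gap]
    provenance[ti[gap], ii[gap], jj[gap]] = PROVENANCE["filled"]

    ds = g.data.assign(
        chlor_a_filled=(("time", "lat", "lon"), filled),
        provenance=(("time", "lat", "lon"), provenance),
    )
    n_filled = int(gap.sum())
    log.info(
        "filled %d gap cells (%d observed kept) in %.1f s",
        n_filled, int(np.isfinite(obs).sum()), _time.perf_counter() - t0,
    )
    return GriddedDataset(ds)


def generalization_experiment(
    g: GriddedDataset,
    train_years: list[int],
    validation_years: list[int],
    arch: Architecture | None = None,
    base_seed: int = 0,
    opts: TrainingOptions | None = None,
    day_denominator: int = 366,
) -> dict:
    """Train on given years, score daily correlation everywhere.

    Returns a dict with the per-day metric ``series`` (whole record) and a
    ``summary`` frame of mean bias/RMSE/CC for the training period and for
    each validation year.  Train and validation years must be disjoint.
    """
    overlap = set(train_years) & set(validation_years)
    if overlap:
        raise ValueError(f"train/validation years overlap: {sorted(overlap)}")
    records = assemble_records(g)
    sub = records[records["year"].isin(train_years)]
    ens = train_gapfill_ensemble(
        sub, arch=arch, n_members=1, base_seed=base_seed, opts=opts,
        day_denominator=day_denominator,
    )
    labelled = records[np.isfinite(records[TARGET_NAME].to_numpy())].copy()
    labelled["pred"] = predict_records(ens, labelled, day_denominator)
    series = daily_metric_series(labelled)
    series["year"] = labelled.groupby("time")["year"].first().reindex(series.index)

    rows = []
    periods = [("train", train_years)] + [(str(y), [y]) for y in validation_years]
    for name, years in periods:
        sel = labelled[labelled["year"].isin(years)]
        m = compute_metrics(sel["pred"].to_numpy(), sel[TARGET_NAME].to_numpy())
        rows.append({"period": name, "bias": m.bias, "rmse": m.rmse, "cc": m.cc, "n": m.n})
    return {"ensemble": ens, "series": series, "summary": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# experiment configuration

@dataclass
class ExperimentConfig:
    """Serializable description of one run (so results are reproducible)."""

    input_path: str | None = None
    output_dir: str = "ocgapfill_out"
    arch: tuple[int, int, int] = (23, 30, 1)
    n_members: int = 6
    base_seed: int = 0
    day_denominator: int = 366
    threshold: float = 1.0
    max_epochs: int = 200
    patience: int = 50
    learning_rate: float = 5e-3
    batch_size: int = 2048
    split_mode: str = "alternating"
    train_years: list[int] | None = None
    validation_years: list[int] | None = None

    def validate(self) -> None:
        if len(self.arch) != 3 or any(v < 1 for v in self.arch):
            raise ValueError(f"arch must be three positive integers, got {self.arch}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.day_denominator not in (365, 366):
            raise ValueError("day_denominator must be 365 or 366")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        SplitSpec(self.split_mode, self.train_years, self.validation_years)

    def training_options(self) -> TrainingOptions:
        return TrainingOptions(
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.base_seed,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
        )

    def architecture(self) -> Architecture:
        return Architecture(*self.arch)

    def split(self) -> SplitSpec:
        return SplitSpec(self.split_mode, self.train_years, self.validation_years)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["arch"] = list(d["arch"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "arch" in d:
            d["arch"] = tuple(d["arch"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
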