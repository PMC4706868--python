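"""Ensembles of identically architected networks.

A single network is a poor emulator of a noisy (stochastic) mapping: each
training run lands in a different local minimum of the error surface and its
Jacobian is an ill-posed derivative of a statistical fit.  Training several
networks that differ only in their random initial weights and averaging their
outputs damps the random component of the error, and averaging their Jacobians
regularizes the sensitivity estimate.  The default ensemble size is six.

Members see identical training data (no bagging); only the initialization
seed differs, so the ensemble is fully reproducible from a base seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import INPUT_NAMES, Standardizer
from .mlp import (
    Architecture,
    MLPParams,
    TrainingHistory,
    TrainingOptions,
    load_model,
    mlp_forward,
    mlp_jacobian,
    save_model,
    train_mlp,
)

__all__ = [
    "Ensemble",
    "SensitivityReport",
    "train_ensemble",
    "ensemble_predict",
    "ensemble_jacobian",
    "save_ensemble",
    "load_ensemble",
]

DEFAULT_N_MEMBERS = 6


@dataclass
class Ensemble:
    """Ordered list of trained members sharing architecture and standardizer."""

    members: list[MLPParams]
    seeds: list[int]
    standardizer: Standardizer | None = None
    histories: list[TrainingHistory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")
        arch = self.members[0].arch
        if any(p.arch != arch for p in self.members):
            raise ValueError("all ensemble members must share one architecture")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("member seeds must be pairwise distinct")
        if len(self.seeds) != len(self.members):
            raise ValueError("one seed per member required")

    @property
    def arch(self) -> Architecture:
        return self.members[0].arch

    def __len__(self) -> int:
        return len(self.members)

    def predict(self, x_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """See :func:`ensemble_predict`."""
        return ensemble_predict(self, x_std)


def train_ensemble(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    arch: Architecture,
    n_members: int = DEFAULT_N_MEMBERS,
    base_seed: int = 0,
    opts: TrainingOptions | None = None,
    standardizer: Standardizer | None = None,
) -> Ensemble:
    """Train ``n_members`` networks from seeds ``base_seed .. base_seed+n-1``.

    Every member sees the same (standardized) train/test data; only the weight
    initialization and the mini-batch shuffling differ, so the members settle
    into different local minima of the error function.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    opts = opts or TrainingOptions()
    members, seeds, histories = [], [], []
    for i in range(n_members):
        seed = base_seed + i
        try:
            params, hist = train_mlp(
                x_train, y_train, x_test, y_test, arch, replace(opts, seed=seed)
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with member context
            raise RuntimeError(f"ensemble member {i} (seed {seed}) failed to train: {exc}") from exc
        members.append(params)
        seeds.append(seed)
        histories.append(hist)
    return Ensemble(members, seeds, standardizer, histories)


def ensemble_predict(e: Ensemble, x_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean prediction and member spread, in physical units.

    ``x_std`` is a standardized input vector or batch.  Returns ``(mean,
    spread)`` where mean is the arithmetic average of member outputs mapped
    back to mg/m^3 (when a target standardizer is attached) and spread is the
    population standard deviation (ddof=0) across members, in the same units.
    """
    preds = np.stack([mlp_forward(p, x_std) for p in e.members])  # (M, ..., m)
    if e.standardizer is not None:
        preds = e.standardizer.inverse_y(preds)
    return preds.mean(axis=0), preds.std(axis=0, ddof=0)


@dataclass
class SensitivityReport:
    """Per-input mean |Jacobian| averaged over members and evaluation records.

    ``values[i]`` is the mean absolute sensitivity of the output to input
    ``i+1``; ``ranking`` lists 1-based input indices in descending order of
    that value.
    """

    values: np.ndarray
    names: list[str]
    physical_units: bool = False

    @property
    def ranking(self) -> np.ndarray:
        # stable sort so exact ties break toward the lower input index
        return np.argsort(-self.values, kind="stable") + 1

    @property
    def top_input(self) -> int:
        return int(self.ranking[0])

    def to_frame(self) -> pd.DataFrame:
        ranks = np.empty(len(self.values), dtype=int)
        ranks[self.ranking - 1] = np.arange(1, len(self.values) + 1)
        return pd.DataFrame(
            {
                "input_index": np.arange(1, len(self.values) + 1),
                "name": self.names,
                "mean_abs_jacobian": self.values,
                "rank": ranks,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ensemble_jacobian(
    e: Ensemble,
    x_std: np.ndarray,
    physical_units: bool = False,
    names: list[str] | None = None,
) -> SensitivityReport:
    """Ensemble-averaged input sensitivity over an evaluation set.

    For each member the analytic Jacobian is evaluated at every record of
    ``x_std`` (standardized input space); absolute values are averaged over
    records, then over members.  Standardized space is the default so inputs
    with different physical units are comparable; ``physical_units=True``
    converts to mg/m^3 per physical input unit via the stored standardizer.
    """
    x_std = np.atleast_2d(np.asarray(x_std, dtype=float))
    if x_std.shape[0] == 0:
        raise ValueError("evaluation set is empty")
    per_member = []
    for p in e.members:
        jac = mlp_jacobian(p, x_std)  # (N, m, n)
        per_member.append(np.abs(jac).mean(axis=(0, 1)))
    values = np.mean(per_member, axis=0)  # (n,)
    if physical_units:
        if e.standardizer is None:
            raise ValueError("physical_units requires an attached standardizer")
        values = values * e.standardizer.y_scale / e.standardizer.x_scale
    if names is None:
        names = INPUT_NAMES if len(values) == len(INPUT_NAMES) else [
            f"x{i}" for i in range(1, len(values) + 1)
        ]
    return SensitivityReport(values=values, names=list(names), physical_units=physical_units)


# ---------------------------------------------------------------------------
# serialization: directory of member model files + manifest

def save_ensemble(dirpath, e: Ensemble, meta: dict | None = None) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (p, seed) in enumerate(zip(e.members, e.seeds)):
        fname = f"member_{i:02d}.json"
        save_model(d / fname, p, standardizer=None, meta={"seed": seed})
        files.append(fname)
    manifest = {
        "format": "ocgapfill-ensemble-1",
        "members": files,
        "seeds": e.seeds,
        "standardizer": e.standardizer.to_dict() if e.standardizer else None,
        "meta": meta or {},
    }
    (d / "manifest.json").write_text(json.dumps(manifest))


def load_ensemble(dirpath) -> Ensemble:
    d = Path(dirpath)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("format") != "ocgapfill-ensemble-1":
        raise ValueError(f"{dirpath}: not a recognized ensemble directory")
    members = [load_model(d / f)[0] for f in manifest["members"]]
    std = Standardizer.from_dict(manifest["standardizer"]) if manifest["standardizer"] else None
    return Ensemble(members, list(manifest["seeds"]), std)
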