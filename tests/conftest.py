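"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ocgapfill.ensemble import train_ensemble
from ocgapfill.features import INPUT_NAMES, TARGET_NAME
from ocgapfill.mlp import Architecture, TrainingOptions
from ocgapfill.pipeline import alternating_split, assemble_records, prepare_training
from ocgapfill.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_synth():
    """A compact synthetic ocean: 60 days, default grid, no predictor gaps."""
    cfg = SynthConfig(n_days=60, gap_fraction=0.2, predictor_gap_fraction=0.0, seed=42)
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_ensemble(small_synth):
    """A 2-member ensemble trained briefly on the compact ocean.

    Training is short (30 epochs, k=6): enough to be a meaningful model for
    algebraic/structural tests without slowing the suite.
    """
    _, g = small_synth
    records = assemble_records(g)
    train, test = alternating_split(records)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # constant 'year' column
        xs_tr, ys_tr, xs_te, ys_te, std = prepare_training(train, test)
    ens = train_ensemble(
        xs_tr, ys_tr, xs_te, ys_te,
        Architecture(len(INPUT_NAMES), 6, 1),
        n_members=2, base_seed=7,
        opts=TrainingOptions(max_epochs=30, patience=10),
        standardizer=std,
    )
    return {
        "ensemble": ens,
        "x_test": xs_te,
        "y_test_std": ys_te,
        "test_frame": test,
        "obs": test[TARGET_NAME].to_numpy(),
        "truth": test["chla_true"].to_numpy(),
    }
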