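"""Single-hidden-layer tanh perceptron: forward pass, analytic Jacobian, training.

The regression model is the classical multilayer perceptron with one hidden
layer of ``k`` hyperbolic-tangent units and a linear output layer,

    y_q = a_q0 + sum_j a_qj * tanh(b_j0 + sum_i b_ji * x_i),

where ``a`` (shape ``(m, k+1)``) holds the output weights and biases and ``b``
(shape ``(k, n+1)``) the hidden weights and biases.  With enough hidden units
this family approximates any continuous mapping, which is why it is the
work-horse for emulating the nonlinear physics->chlorophyll relationship.

Training minimizes the mean squared error E = (1/N) * sum_i (Y_i - NN(X_i))^2
with a seeded mini-batch Adam optimizer and early stopping on a held-out test
set: the weights returned are those of the epoch with minimum test error.
Everything here is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Architecture",
    "MLPParams",
    "TrainingOptions",
    "TrainingHistory",
    "init_weights",
    "mlp_forward",
    "mlp_jacobian",
    "error_function",
    "train_mlp",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class Architecture:
    """Network shape n:k:m (inputs : hidden tanh units : linear outputs)."""

    n_inputs: int
    n_hidden: int
    n_outputs: int = 1

    def __post_init__(self) -> None:
        for name in ("n_inputs", "n_hidden", "n_outputs"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    def __str__(self) -> str:  # e.g. "23:30:1"
        return f"{self.n_inputs}:{self.n_hidden}:{self.n_outputs}"


@dataclass
class MLPParams:
    """Weight matrices of one network.

    ``hidden_weights`` has shape ``(k, n+1)``; column 0 is the hidden bias
    b_j0.  ``output_weights`` has shape ``(m, k+1)``; column 0 is the output
    bias a_q0.
    """

    arch: Architecture
    hidden_weights: np.ndarray
    output_weights: np.ndarray

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        k, n, m = self.arch.n_hidden, self.arch.n_inputs, self.arch.n_outputs
        if self.hidden_weights.shape != (k, n + 1):
            raise ValueError(
                f"hidden_weights shape {self.hidden_weights.shape} != {(k, n + 1)}"
            )
        if self.output_weights.shape != (m, k + 1):
            raise ValueError(
                f"output_weights shape {self.output_weights.shape} != {(m, k + 1)}"
            )
        if not (
            np.all(np.isfinite(self.hidden_weights))
            and np.all(np.isfinite(self.output_weights))
        ):
            raise ValueError("weights must be finite")

    def copy(self) -> "MLPParams":
        return MLPParams(self.arch, self.hidden_weights.copy(), self.output_weights.copy())


@dataclass
class TrainingOptions:
    """Hyper-parameters of the seeded Adam + early-stopping loop.

    ``patience`` is the number of epochs without test-set improvement before
    training halts; the returned weights are always those of the best epoch.
    ``target_error`` is an optional stopping bound on the test-set mean
    squared error (off by default; early stopping is the primary criterion).
    ``batch_size=None`` selects full-batch updates.
    """

    max_epochs: int = 200
    patience: int = 50
    seed: int = 0
    learning_rate: float = 5e-3
    batch_size: int | None = 2048
    target_error: float | None = None

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 1 <= self.patience <= self.max_epochs:
            raise ValueError("patience must satisfy 1 <= patience <= max_epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.target_error is not None and self.target_error < 0:
            raise ValueError("target_error must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch train/test mean squared errors; epoch 0 is the initial state."""

    train_errors: list[float] = field(default_factory=list)
    test_errors: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def final_test_rmse(self) -> float:
        return float(np.sqrt(self.test_errors[self.best_epoch]))


def init_weights(arch: Architecture, seed: int) -> MLPParams:
    """Zero-mean random weights scaled by 1/sqrt(fan-in), deterministic in seed."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, 1.0 / np.sqrt(arch.n_inputs + 1), size=(arch.n_hidden, arch.n_inputs + 1))
    a = rng.normal(0.0, 1.0 / np.sqrt(arch.n_hidden + 1), size=(arch.n_outputs, arch.n_hidden + 1))
    return MLPParams(arch, b, a)


def _as_batch(params: MLPParams, x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != params.arch.n_inputs:
        raise ValueError(
            f"input has {x.shape[-1] if x.ndim else 0} features, "
            f"network expects {params.arch.n_inputs}"
        )
    return x, single


def _hidden(params: MLPParams, x2d: np.ndarray) -> np.ndarray:
    b = params.hidden_weights
    return np.tanh(x2d @ b[:, 1:].T + b[:, 0])


def mlp_forward(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """Evaluate the network.  ``x`` is ``(n,)`` or ``(N, n)``; output matches."""
    x2d, single = _as_batch(params, x)
    a = params.output_weights
    y = _hidden(params, x2d) @ a[:, 1:].T + a[:, 0]
    return y[0] if single else y


def mlp_jacobian(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """Analytic derivative of the outputs with respect to the inputs.

    Differentiating the model directly gives

        dy_q/dx_s = sum_j a_qj * (1 - t_j^2) * b_js,
        t_j = tanh(b_j0 + sum_i b_ji x_i).

    Returns ``(m, n)`` for a single input vector, ``(N, m, n)`` for a batch.
    """
    x2d, single = _as_batch(params, x)
    a = params.output_weights[:, 1:]  # (m, k)
    b = params.hidden_weights[:, 1:]  # (k, n)
    t = _hidden(params, x2d)  # (N, k)
    jac = np.einsum("qj,Nj,js->Nqs", a, 1.0 - t**2, b)
    return jac[0] if single else jac


def error_function(params: MLPParams, x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error E = (1/N) sum_i (Y_i - NN(X_i))^2 over the records."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 2 and x.shape[0] == 0 or x.size == 0:
        raise ValueError("error_function requires at least one record")
    pred = mlp_forward(params, x)
    if y.ndim == 1 and pred.ndim == 2 and pred.shape[1] == 1:
        pred = pred[:, 0]
    return float(np.mean((y - pred) ** 2))


def _check_xy(x: np.ndarray, y: np.ndarray, arch: Architecture, name: str):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] == 0:
        raise ValueError(f"{name} set is empty")
    if x.shape[1] != arch.n_inputs or y.shape[1] != arch.n_outputs:
        raise ValueError(f"{name} set shape mismatch with architecture {arch}")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"{name} set has {x.shape[0]} inputs but {y.shape[0]} targets")
    return x, y


def train_mlp(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    arch: Architecture,
    opts: TrainingOptions | None = None,
) -> tuple[MLPParams, TrainingHistory]:
    """Fit the network by seeded mini-batch Adam with early stopping.

    Inputs are expected pre-standardized (see :mod:`ocgapfill.features`).
    The test set steers early stopping: the parameters returned are those of
    the epoch attaining the minimum recorded test error, so the reported model
    is never worse on the test set than the initial random weights.
    """
    opts = opts or TrainingOptions()
    x_train, y_train = _check_xy(x_train, y_train, arch, "train")
    x_test, y_test = _check_xy(x_test, y_test, arch, "test")

    params = init_weights(arch, opts.seed)
    rng = np.random.default_rng(np.random.SeedSequence([opts.seed, 0x0C6F]))

    n_train = x_train.shape[0]
    batch = opts.batch_size or n_train
    batch = min(batch, n_train)

    # Adam state for the two weight matrices.
    mats = [params.hidden_weights, params.output_weights]
    m_t = [np.zeros_like(w) for w in mats]
    v_t = [np.zeros_like(w) for w in mats]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = TrainingHistory()
    history.train_errors.append(error_function(params, x_train, y_train))
    history.test_errors.append(error_function(params, x_test, y_test))
    best = params.copy()
    best_err = history.test_errors[0]
    history.best_epoch = 0
    since_best = 0

    for epoch in range(1, opts.max_epochs + 1):
        order = rng.permutation(n_train)
        for lo in range(0, n_train, batch):
            idx = order[lo : lo + batch]
            xb, yb = x_train[idx], y_train[idx]
            t = _hidden(params, xb)
            a = params.output_weights
            pred = t @ a[:, 1:].T + a[:, 0]
            resid = pred - yb  # (B, m)
            nb = xb.shape[0]
            # gradients of mean squared error
            g_out = np.empty_like(a)
            g_out[:, 0] = 2.0 / nb * resid.sum(axis=0)
            g_out[:, 1:] = 2.0 / nb * resid.T @ t
            delta = (resid @ a[:, 1:]) * (1.0 - t**2)  # (B, k)
            g_hid = np.empty_like(params.hidden_weights)
            g_hid[:, 0] = 2.0 / nb * delta.sum(axis=0)
            g_hid[:, 1:] = 2.0 / nb * delta.T @ xb
            step += 1
            for w, g, mm, vv in zip(mats, (g_hid, g_out), m_t, v_t):
                mm *= beta1
                mm += (1 - beta1) * g
                vv *= beta2
                vv += (1 - beta2) * g**2
                mhat = mm / (1 - beta1**step)
                vhat = vv / (1 - beta2**step)
                w -= opts.learning_rate * mhat / (np.sqrt(vhat) + eps)

        e_train = error_function(params, x_train, y_train)
        e_test = error_function(params, x_test, y_test)
        if not (np.isfinite(e_train) and np.isfinite(e_test)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} "
                f"(train E={e_train!r}, test E={e_test!r}); "
                f"lower the learning rate ({opts.learning_rate}) or check input scaling"
            )
        history.train_errors.append(e_train)
        history.test_errors.append(e_test)
        if e_test < best_err:
            best_err = e_test
            best = params.copy()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if opts.target_error is not None and best_err <= opts.target_error:
            break
        if since_best >= opts.patience:
            break

    return best, history


# ---------------------------------------------------------------------------
# serialization

_FORMAT = "ocgapfill-mlp-1"


def save_model(
    path: str | Path,
    params: MLPParams,
    standardizer=None,
    meta: dict | None = None,
) -> None:
    """Write a self-describing JSON model file (lossless float round-trip)."""
    doc = {
        "format": _FORMAT,
        "arch": [params.arch.n_inputs, params.arch.n_hidden, params.arch.n_outputs],
        "hidden_weights": params.hidden_weights.tolist(),
        "output_weights": params.output_weights.tolist(),
        "standardizer": standardizer.to_dict() if standardizer is not None else None,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path):
    """Read a model file; returns ``(MLPParams, Standardizer | None, meta)``."""
    from .features import Standardizer

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a recognized model file")
    arch = Architecture(*doc["arch"])
    params = MLPParams(arch, np.array(doc["hidden_weights"]), np.array(doc["output_weights"]))
    std = Standardizer.from_dict(doc["standardizer"]) if doc["standardizer"] else None
    return params, std, doc.get("meta", {})
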