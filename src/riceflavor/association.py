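"""Volatile ↔ functional-component association.

Two views are provided.  The *pairwise* view correlates each chemical
class's total content with each functional component (resistant starch %,
fat acidity mg/100 g) across samples — plain Pearson r.  The *model* view
trains a small feed-forward regression network (one hidden layer of 4
units, symmetric-sigmoid hidden activation, linear output) on compound
relative contents and scores it by the Pearson correlation R between
observed and predicted component values, either on the training samples or
by leave-one-out refitting.

The network is deliberately minimal and fully deterministic: inputs are
scaled to [-1, 1] per feature, targets are standardized internally (R is
invariant to that affine map), weights start uniform in
[-init_scale, init_scale] from a seeded generator, and training is batch
gradient descent on mean squared error with a fixed learning rate.  The
symmetric sigmoid 2/(1+e^(-2x))-1 is computed as tanh(x), to which it is
mathematically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ValidationError

Params = tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]  # W1, b1, W2, b2


@dataclass
class NetConfig:
    """Hyperparameters of the regression network.

    ``n_hidden`` defaults to the study architecture (4 units).  The
    learning rate applies to already-scaled inputs/targets, so the default
    is robust across data scales.  ``tol`` stops training early when the
    epoch-to-epoch loss improvement falls below it.
    """

    n_inputs: int
    n_outputs: int = 1
    n_hidden: int = 4
    learning_rate: float = 0.05
    max_epochs: int = 5000
    tol: float = 1e-12
    seed: int = 0
    init_scale: float = 0.5
    scale_inputs: bool = True
    scale_outputs: bool = True

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValidationError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")


# ---------------------------------------------------------------------------
# raw network functions (operate on pre-scaled arrays; used by fit and by
# the finite-difference gradient tests)
# ---------------------------------------------------------------------------


def init_params(config: NetConfig) -> Params:
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    W1 = rng.uniform(-s, s, size=(config.n_hidden, config.n_inputs))
    b1 = rng.uniform(-s, s, size=config.n_hidden)
    W2 = rng.uniform(-s, s, size=(config.n_outputs, config.n_hidden))
    b2 = rng.uniform(-s, s, size=config.n_outputs)
    return W1, b1, W2, b2


def forward(params: Params, X: np.ndarray) -> np.ndarray:
    """Network output for inputs X (n_samples x n_inputs)."""
    W1, b1, W2, b2 = params
    H = np.tanh(X @ W1.T + b1)
    return H @ W2.T + b2


def loss(params: Params, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean squared error over samples and outputs."""
    diff = forward(params, X) - Y
    return float(np.mean(diff**2))


def gradient(params: Params, X: np.ndarray, Y: np.ndarray) -> Params:
    """Analytic backpropagation gradient of :func:`loss`."""
    W1, b1, W2, b2 = params
    n, _ = X.shape
    H = np.tanh(X @ W1.T + b1)
    out = H @ W2.T + b2
    dOut = 2.0 * (out - Y) / out.size
    dW2 = dOut.T @ H
    db2 = dOut.sum(axis=0)
    dH = dOut @ W2
    dZ = dH * (1.0 - H**2)
    dW1 = dZ.T @ X
    db1 = dZ.sum(axis=0)
    return dW1, db1, dW2, db2


class _MinMaxScaler:
    """Per-feature affine map onto [-1, 1]; constant features map to 0."""

    def __init__(self, X: np.ndarray) -> None:
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        span = self.hi - self.lo
        self.span = np.where(span == 0, 1.0, span)
        self.constant = span == 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = 2.0 * (X - self.lo) / self.span - 1.0
        Z[:, self.constant] = 0.0
        return Z


class _Standardizer:
    def __init__(self, Y: np.ndarray) -> None:
        self.mean = Y.mean(axis=0)
        sd = Y.std(axis=0)
        self.sd = np.where(sd == 0, 1.0, sd)

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.mean) / self.sd

    def inverse(self, Y: np.ndarray) -> np.ndarray:
        return Y * self.sd + self.mean


@dataclass
class TrainedNet:
    """A fitted network plus its loss trace and preprocessing state."""

    params: Params
    config: NetConfig
    loss_trace: np.ndarray
    x_scaler: _MinMaxScaler | None
    y_scaler: _Standardizer | None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.n_inputs:
            raise ValidationError(
                f"X must be 2-D with {self.config.n_inputs} columns, got {X.shape}"
            )
        Z = self.x_scaler.transform(X) if self.x_scaler else X
        out = forward(self.params, Z)
        return self.y_scaler.inverse(out) if self.y_scaler else out


def fit_bpnn(X: np.ndarray, y: np.ndarray, config: NetConfig) -> TrainedNet:
    """Train the network by batch gradient descent on mean squared error.

    Deterministic given ``config.seed``.  Raises on non-finite loss, which
    indicates a learning rate too large for the data.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or len(X) != len(Y):
        raise ValidationError("X must be 2-D and aligned with y")
    if len(X) < 2:
        raise ValidationError("need at least 2 samples to fit")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValidationError("X and y must be finite (no missing values)")
    if X.shape[1] != config.n_inputs or Y.shape[1] != config.n_outputs:
        raise ValidationError(
            f"config expects {config.n_inputs} inputs / {config.n_outputs} outputs, "
            f"data has {X.shape[1]} / {Y.shape[1]}"
        )

    x_scaler = _MinMaxScaler(X) if config.scale_inputs else None
    y_scaler = _Standardizer(Y) if config.scale_outputs else None
    Xs = x_scaler.transform(X) if x_scaler else X
    Ys = y_scaler.transform(Y) if y_scaler else Y

    params = init_params(config)
    trace = [loss(params, Xs, Ys)]
    lr = config.learning_rate
    for epoch in range(config.max_epochs):
        grads = gradient(params, Xs, Ys)
        params = tuple(p - lr * g for p, g in zip(params, grads))  # type: ignore[assignment]
        cur = loss(params, Xs, Ys)
        if not np.isfinite(cur):
            raise ValidationError(
                f"training diverged at epoch {epoch + 1} (learning_rate={lr}); "
                "reduce the learning rate"
            )
        trace.append(cur)
        if trace[-2] - cur < config.tol and cur <= trace[-2]:
            break
    return TrainedNet(
        params=params, config=config, loss_trace=np.array(trace),
        x_scaler=x_scaler, y_scaler=y_scaler,
    )


# ---------------------------------------------------------------------------
# correlation R
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float | None, bool]:
    """Pearson r with an explicit undefined flag for zero-variance input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return None, False
    r = float(np.corrcoef(a, b)[0, 1])
    return r, True


@dataclass
class AssociationResult:
    """Per-component correlation R (model view) and/or pairwise class
    correlations.  Undefined correlations carry r=None with defined=False
    rather than a silent 0."""

    per_component: dict[str, dict] = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None
    mode: str | None = None


def class_functional_correlation(
    summary: pd.DataFrame, functional: pd.DataFrame
) -> AssociationResult:
    """Pearson r between each class's total content and each functional
    component, across the samples common to both tables.

    ``summary`` is the long class-summary frame (sample, chem_class,
    n_compounds, total_content); ``functional`` has sample,
    resistant_starch, fat_acidity.  Needs >= 3 shared samples.
    """
    from .core import FUNCTIONAL_COMPONENTS

    wide = summary.pivot(index="sample", columns="chem_class", values="total_content")
    func = functional.set_index("sample")
    shared = [s for s in wide.index if s in func.index]
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 samples shared between inputs, got {len(shared)}"
        )
    wide = wide.loc[shared]
    func = func.loc[shared]
    rows = []
    for cls in wide.columns:
        for comp in FUNCTIONAL_COMPONENTS:
            r, defined = _pearson(wide[cls].to_numpy(), func[comp].to_numpy())
            rows.append(
                {"chem_class": cls, "component": comp, "r": r, "defined": defined}
            )
    return AssociationResult(pairwise=pd.DataFrame(rows))


def association_r(
    net: TrainedNet,
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "training",
    component_names: Sequence[str] | None = None,
) -> AssociationResult:
    """Correlation R between observed and predicted component values.

    ``mode="training"`` scores the fitted net on the given samples;
    ``mode="leave_one_out"`` refits the same configuration once per held-out
    sample (>= 3 samples required) and correlates the held-out predictions
    with the observations.  The mode is recorded in the result.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if component_names is None:
        component_names = [f"component_{i}" for i in range(Y.shape[1])]
    if len(component_names) != Y.shape[1]:
        raise ValidationError("component_names length must match y columns")

    if mode == "training":
        pred = net.predict(X)
    elif mode == "leave_one_out":
        if len(X) < 3:
            raise ValidationError("leave_one_out needs >= 3 samples")
        pred = np.empty_like(Y)
        for i in range(len(X)):
            keep = np.arange(len(X)) != i
            fold = fit_bpnn(X[keep], Y[keep], net.config)
            pred[i] = fold.predict(X[i : i + 1])[0]
    else:
        raise ValidationError(f"mode must be 'training' or 'leave_one_out', got {mode!r}")

    per_component = {}
    for j, name in enumerate(component_names):
        r, defined = _pearson(Y[:, j], pred[:, j])
        per_component[name] = {"r": r, "defined": defined, "mode": mode}
    return AssociationResult(per_component=per_component, mode=mode)
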